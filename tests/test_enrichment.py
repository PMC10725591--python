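"""Two-sided hypergeometric enrichment, kappa agreement, term grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from traplfq import (
    enrich,
    enrichment_with_groups,
    group_terms,
    hypergeom_two_sided,
    kappa_score,
    read_gmt,
    simulate_terms,
    write_gmt,
)
from traplfq.enrichment import Term, TermCatalog


def pmf_enumeration(k, n, K, N):
    """Exact tails by direct summation of the hypergeometric pmf."""
    def pmf(x):
        return comb(K, x, exact=True) * comb(N - K, n - x, exact=True) / comb(N, n, exact=True)

    lo, hi = max(0, n - (N - K)), min(n, K)
    p_ge = sum(pmf(x) for x in range(k, hi + 1))
    p_le = sum(pmf(x) for x in range(lo, k + 1))
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestHypergeom:
    def test_point_mass_capped_at_one(self):
        p, direction = hypergeom_two_sided(5, 5, 5, 5)
        assert p == 1.0 and direction == "enriched"

    def test_worked_example(self):
        # N=10, K=5, n=4, k=4: P(X>=4) = 5/210, doubled
        p, direction = hypergeom_two_sided(4, 4, 5, 10)
        assert p == pytest.approx(2 * 5 / 210, rel=1e-12)
        assert direction == "enriched"

    def test_at_the_mean_p_near_one(self):
        # N=10, K=5, n=4 -> mean 2; k=2 sits at the expectation
        p, direction = hypergeom_two_sided(2, 4, 5, 10)
        assert direction == "enriched"  # tie resolves to enriched
        assert p == 1.0

    def test_below_mean_is_depleted(self):
        _, direction = hypergeom_two_sided(0, 4, 5, 10)
        assert direction == "depleted"

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_two_sided(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_two_sided(1, 4, 11, 10)

    def test_exact_against_enumeration_all_small_instances(self):
        """Machine-precision agreement with full pmf enumeration, N <= 25."""
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        p, _ = hypergeom_two_sided(k, n, K, N)
                        assert p == pytest.approx(
                            pmf_enumeration(k, n, K, N), rel=1e-10, abs=1e-14
                        ), (k, n, K, N)


class TestKappa:
    UNIVERSE = frozenset(f"g{i}" for i in range(1, 6))

    def test_identical_sets(self):
        a = {"g1", "g2"}
        assert kappa_score(a, a, self.UNIVERSE) == pytest.approx(1.0)

    def test_worked_example(self):
        # universe of 5, A={g1,g2}, B={g3,g4}: kappa = -2/3
        assert kappa_score({"g1", "g2"}, {"g3", "g4"}, self.UNIVERSE) == pytest.approx(-2 / 3)

    def test_degenerate_marginals(self):
        # both terms cover the whole universe: p_e = 1 but agreement perfect
        assert kappa_score(self.UNIVERSE, self.UNIVERSE, self.UNIVERSE) == 1.0

    @given(st.sets(st.sampled_from(sorted(UNIVERSE)), min_size=1, max_size=4))
    @settings(max_examples=40, deadline=None)
    def test_complement_is_nonpositive(self, a):
        b = set(self.UNIVERSE) - a
        assert kappa_score(a, b, self.UNIVERSE) <= 1e-12

    @given(
        st.sets(st.sampled_from(sorted(UNIVERSE)), max_size=5),
        st.sets(st.sampled_from(sorted(UNIVERSE)), max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, a, b):
        assert kappa_score(a, b, self.UNIVERSE) == pytest.approx(
            kappa_score(b, a, self.UNIVERSE)
        )


def catalog_from(genesets, universe):
    terms = [Term(tid, tid, frozenset(g)) for tid, g in genesets.items()]
    return TermCatalog(terms=terms, universe=frozenset(universe))


class TestGroupTerms:
    def _rows(self, term_ids, qs=None):
        qs = qs if qs is not None else [0.01] * len(term_ids)
        return pd.DataFrame({"term_id": term_ids, "q": qs})

    def test_disjoint_terms_are_singletons(self):
        universe = [f"g{i}" for i in range(20)]
        cat = catalog_from({"A": universe[:5], "B": universe[10:15]}, universe)
        groups = group_terms(self._rows(["A", "B"]), cat, set(universe[:5]))
        assert sorted(g.member_term_ids for g in groups) == [["A"], ["B"]]

    def test_identical_terms_one_group_leading_by_q(self):
        universe = [f"g{i}" for i in range(10)]
        gs = universe[:4]
        cat = catalog_from({"A": gs, "B": gs, "C": gs}, universe)
        groups = group_terms(self._rows(["A", "B", "C"], [0.03, 0.01, 0.02]),
                             cat, set(gs))
        assert len(groups) == 1
        assert groups[0].member_term_ids == ["A", "B", "C"]
        assert groups[0].leading_term_id == "B"  # equal overlap, smallest q

    def test_chain_merges_by_connected_components(self):
        # A-B and B-C agree above threshold, A-C far below: one group of 3
        universe = [f"g{i}" for i in range(12)]
        a = set(universe[0:6])
        b = set(universe[2:8])     # kappa(A,B) = 1/3... choose overlap for >= 0.4
        cat = catalog_from({"A": universe[0:6], "B": universe[1:7], "C": universe[2:8]},
                           universe)
        ka = kappa_score(set(universe[0:6]), set(universe[1:7]), cat.universe)
        kac = kappa_score(set(universe[0:6]), set(universe[2:8]), cat.universe)
        assert ka >= 0.4 > kac
        groups = group_terms(self._rows(["A", "B", "C"]), cat, set(universe[0:6]))
        assert len(groups) == 1
        assert groups[0].member_term_ids == ["A", "B", "C"]

    def test_order_invariance(self):
        universe = [f"g{i}" for i in range(12)]
        cat = catalog_from(
            {"A": universe[0:6], "B": universe[1:7], "C": universe[8:11]}, universe
        )
        q = {"A": 0.01, "B": 0.02, "C": 0.03}
        for perm in (["A", "B", "C"], ["C", "B", "A"], ["B", "A", "C"]):
            groups = group_terms(self._rows(perm, [q[t] for t in perm]),
                                 cat, set(universe[0:6]))
            assert [g.member_term_ids for g in groups] == [["A", "B"], ["C"]]
            assert groups[0].leading_term_id == "A"

    def test_empty_input(self):
        cat = catalog_from({}, ["g1"])
        assert group_terms(pd.DataFrame(columns=["term_id", "q"]), cat, set()) == []


class TestEnrich:
    def test_planted_term_beats_background(self):
        universe = [f"g{i}" for i in range(200)]
        enriched = set(universe[:25])
        cat = simulate_terms(universe, n_terms=20, genes_per_term=15,
                             enriched_term_genes_from=enriched, seed=8)
        df = enrich(enriched, cat)
        planted_p = df.loc[df.term_id == "T0000", "p"].iloc[0]
        background_p = df.loc[df.term_id != "T0000", "p"]
        assert planted_p < background_p.median()

    def test_planted_term_rank_one_across_seeds(self):
        universe = [f"g{i}" for i in range(300)]
        enriched = set(universe[:30])
        wins = 0
        for seed in range(20):
            cat = simulate_terms(universe, n_terms=25, genes_per_term=15,
                                 enriched_term_genes_from=enriched, seed=seed)
            df = enrich(enriched, cat)
            wins += df.sort_values(["q", "p"]).iloc[0].term_id == "T0000"
        assert wins >= 18

    def test_level_filter_applies_only_to_levelled_terms(self):
        universe = [f"g{i}" for i in range(30)]
        terms = [
            Term("T1", "level=2", frozenset(universe[:5]), level=2),
            Term("T2", "level=5", frozenset(universe[:5]), level=5),
            Term("T3", "nolevel", frozenset(universe[:5])),
        ]
        cat = TermCatalog(terms=terms, universe=frozenset(universe))
        df = enrich(set(universe[:5]), cat)
        assert set(df.term_id) == {"T2", "T3"}

    def test_gmt_roundtrip(self, tmp_path):
        universe = [f"g{i}" for i in range(50)]
        cat = simulate_terms(universe, n_terms=5, genes_per_term=8,
                             enriched_term_genes_from=set(universe[:10]), seed=1)
        path = tmp_path / "cat.gmt"
        write_gmt(cat, path)
        back = read_gmt(path, universe=set(universe))
        assert {t.term_id for t in back.terms} == {t.term_id for t in cat.terms}
        for t in cat.terms:
            assert back.get(t.term_id).genes == t.genes

    def test_groups_annotated_on_table(self):
        universe = [f"g{i}" for i in range(100)]
        enriched = set(universe[:20])
        cat = simulate_terms(universe, n_terms=10, genes_per_term=12,
                             enriched_term_genes_from=enriched, seed=2)
        df = enrichment_with_groups(enriched, cat)
        sig = df[df.q < 0.05]
        assert (sig.group_id >= 0).all()
        for gid, sub in sig.groupby("group_id"):
            assert sub.leading.sum() == 1
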