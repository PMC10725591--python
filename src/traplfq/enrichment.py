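"""Hypergeometric term enrichment, kappa-score term grouping, redundancy filter.

Enrichment is the two-sided (enrichment/depletion) hypergeometric test: for a
query of n analyzed genes against a term annotating K of the N universe genes,
with k genes in common, the two-sided p doubles the smaller of the inclusive
tails P(X >= k) and P(X <= k), capped at 1.  Significant terms are grouped by
the chance-corrected agreement (kappa) of their gene memberships over the
analyzed universe, and each group is represented by its leading term — the
member with the largest fraction of its genes overlapping the query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass
class Term:
    term_id: str
    name: str
    genes: frozenset[str]
    level: int | None = None


@dataclass
class TermCatalog:
    """A set of gene-annotation terms over a gene universe."""

    terms: list[Term]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("term ids must be unique")
        for t in self.terms:
            if not t.genes <= self.universe:
                raise ValueError(f"term {t.term_id} has genes outside the universe")

    def get(self, term_id: str) -> Term:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass
class TermGroup:
    member_term_ids: list[str]
    leading_term_id: str
    kappa: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def read_gmt(path: str | Path, universe: set[str] | None = None) -> TermCatalog:
    """Read a GMT file (term_id <tab> name <tab> gene...) into a catalog.

    If ``universe`` is None it defaults to the union of all term genes.
    """
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
        level = None
        name = parts[1]
        if name.startswith("level="):
            level = int(name.split("=", 1)[1])
        terms.append(Term(parts[0], name, frozenset(parts[2:]), level=level))
    if universe is None:
        universe = set().union(*(t.genes for t in terms)) if terms else set()
    return TermCatalog(terms=terms, universe=frozenset(universe))


def write_gmt(catalog: TermCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.name, *sorted(t.genes)]) for t in catalog.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_two_sided(k: int, n: int, K: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric p-value and direction for one term.

    X ~ Hypergeometric(N, K, n); p = min(1, 2*min(P(X >= k), P(X <= k))).
    Direction is "depleted" when k lies strictly below the expectation
    n*K/N, "enriched" otherwise.
    """
    if not (0 <= k <= min(n, K)) or K > N or n > N or min(k, n, K, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    rv = hypergeom(N, K, n)
    p_enrich = float(rv.sf(k - 1))   # P(X >= k), inclusive
    p_deplete = float(rv.cdf(k))     # P(X <= k), inclusive
    p = min(1.0, 2.0 * min(p_enrich, p_deplete))
    direction = "depleted" if k < n * K / N else "enriched"
    return p, direction


def kappa_score(
    term_a_genes: set[str] | frozenset[str],
    term_b_genes: set[str] | frozenset[str],
    analyzed_genes: set[str] | frozenset[str],
) -> float:
    """Cohen's kappa between two terms' memberships over the analyzed genes."""
    if not analyzed_genes:
        raise ValueError("analyzed_genes must be nonempty")
    u = set(analyzed_genes)
    a = set(term_a_genes) & u
    b = set(term_b_genes) & u
    total = len(u)
    both = len(a & b)
    neither = total - len(a | b)
    p_o = (both + neither) / total
    p_a, p_b = len(a) / total, len(b) / total
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0  # marginals force perfect agreement
        warnings.warn("kappa undefined (p_e = 1 with imperfect agreement); returning 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def enrich(
    query: set[str],
    catalog: TermCatalog,
    min_level: int | None = 3,
    max_level: int | None = 8,
) -> pd.DataFrame:
    """Test every catalog term against the query; BH across all tested terms.

    Terms carrying a level outside [min_level, max_level] are excluded before
    testing; terms without level metadata always pass through.
    """
    universe = catalog.universe
    q = set(query) & universe
    n, N = len(q), len(universe)
    rows = []
    for t in catalog.terms:
        if t.level is not None:
            if min_level is not None and t.level < min_level:
                continue
            if max_level is not None and t.level > max_level:
                continue
        K = len(t.genes)
        k = len(q & t.genes)
        p, direction = hypergeom_two_sided(k, n, K, N)
        rows.append(
            {"term_id": t.term_id, "name": t.name, "k": k, "n": n, "K": K,
             "N": N, "direction": direction, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term_id", "name", "k", "n", "K", "N",
                                     "direction", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def group_terms(
    rows: pd.DataFrame,
    catalog: TermCatalog,
    query: set[str],
    kappa_threshold: float = 0.4,
    merge_overlap: float = 0.5,
) -> list[TermGroup]:
    """Group significant terms by kappa-linked connected components.

    Edges join term pairs with kappa >= ``kappa_threshold``; groups whose
    member-term sets share a Jaccard index >= ``merge_overlap`` are merged
    iteratively to a fixed point.  The leading term maximizes
    |term genes ∩ query| / |term genes|, ties broken by smaller q then
    lexicographic id.  Output order and content are independent of the input
    row order.
    """
    if rows.empty:
        return []
    term_ids = sorted(rows["term_id"])
    q_of = dict(zip(rows["term_id"], rows["q"]))
    genes_of = {tid: catalog.get(tid).genes for tid in term_ids}
    kap = pd.DataFrame(1.0, index=term_ids, columns=term_ids)
    g = nx.Graph()
    g.add_nodes_from(term_ids)
    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            k = kappa_score(genes_of[a], genes_of[b], catalog.universe)
            kap.loc[a, b] = kap.loc[b, a] = k
            if k >= kappa_threshold:
                g.add_edge(a, b)
    groups = [frozenset(c) for c in nx.connected_components(g)]

    def jaccard(x: frozenset, y: frozenset) -> float:
        return len(x & y) / len(x | y)

    merged = True
    while merged:  # fixed point; a no-op on already-disjoint groups
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if jaccard(groups[i], groups[j]) >= merge_overlap:
                    groups[i] = groups[i] | groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break

    out = []
    for members in sorted(groups, key=lambda s: sorted(s)[0]):
        mids = sorted(members)

        def lead_key(tid: str):
            genes = genes_of[tid]
            frac = len(genes & query) / len(genes) if genes else 0.0
            return (-frac, q_of[tid], tid)

        leading = min(mids, key=lead_key)
        out.append(
            TermGroup(member_term_ids=mids, leading_term_id=leading,
                      kappa=kap.loc[mids, mids])
        )
    return out


def enrichment_with_groups(
    query: set[str],
    catalog: TermCatalog,
    q_cut: float = 0.05,
    kappa_threshold: float = 0.4,
    merge_overlap: float = 0.5,
    min_level: int | None = 3,
    max_level: int | None = 8,
) -> pd.DataFrame:
    """Enrichment table annotated with group ids and leading-term flags."""
    df = enrich(query, catalog, min_level=min_level, max_level=max_level)
    df["group_id"] = -1
    df["leading"] = False
    sig = df[df["q"] < q_cut]
    groups = group_terms(sig, catalog, set(query) & catalog.universe,
                         kappa_threshold=kappa_threshold,
                         merge_overlap=merge_overlap)
    for gid, grp in enumerate(groups):
        df.loc[df["term_id"].isin(grp.member_term_ids), "group_id"] = gid
        df.loc[df["term_id"] == grp.leading_term_id, "leading"] = True
    return df
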