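"""Synthetic inputs with the statistical structure the pipeline assumes.

The LFQ generator emulates a pooled-cortex TRAP label-free experiment: the
default design is two groups of 4 samples (five pools per group with one
removed), log-normal protein abundances on the log2 scale, per-sample scale
distortions that median normalization must undo, intensity-dependent
missing-not-at-random dropout (low-abundance cells vanish first, which is
what first-centile imputation presupposes), planted log2 effects for a
fraction of proteins, and 1 + Poisson razor+unique peptide counts so the
>= 2-peptide filter has real work to do.

All randomness flows from a single seed; sub-streams are spawned
deterministically per output, so an identical configuration reproduces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .lfq_io import Design, LfqMatrix
from .netcluster import PpiGraph, graph_from_edges
from .enrichment import Term, TermCatalog

DEFAULT_GROUPS = [("ref", 4), ("test", 4)]


@dataclass
class SimConfig:
    """Parameters of the synthetic LFQ experiment.

    log2-scale parameters: a protein's latent abundance is
    ``Normal(baseline_log2_mean, baseline_log2_sd)``; each cell adds the
    planted group effect, its sample's scale offset and
    ``Normal(0, noise_log2_sd)`` measurement noise, then exponentiates.
    A cell goes missing with probability
    ``logistic((mnar_midpoint_log2 - log2 intensity) * mnar_slope)``.
    """

    n_proteins: int = 2000
    groups: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.5
    effect_log2: float = 2.0
    frac_de: float = 0.1
    sample_scale_log2: list[float] | None = None
    mnar_midpoint_log2: float = 22.0
    mnar_slope: float = 2.0
    peptide_count_mean: float = 4.0
    frac_reverse: float = 0.01
    frac_contaminant: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("sample counts must be positive")
        if self.baseline_log2_sd <= 0 or self.mnar_slope <= 0:
            raise ValueError("sd and slope parameters must be > 0")
        if self.noise_log2_sd < 0 or self.peptide_count_mean < 1:
            raise ValueError("noise sd >= 0 and peptide_count_mean >= 1 required")
        n_samples = sum(n for _, n in self.groups)
        if self.sample_scale_log2 is not None and len(self.sample_scale_log2) != n_samples:
            raise ValueError("sample_scale_log2 length must equal total sample count")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    def design(self) -> Design:
        group_of = {}
        for label, n in self.groups:
            for r in range(1, n + 1):
                group_of[f"{label}_{r}"] = label
        comparisons = [
            (label, self.groups[0][0]) for label, _ in self.groups[1:]
        ]
        return Design(group_of=group_of, comparisons=comparisons)


@dataclass
class GroundTruth:
    de_protein_ids: set[str]
    true_effect_log2: dict[str, float]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_lfq(config: SimConfig) -> tuple[LfqMatrix, GroundTruth]:
    """Generate an LfqMatrix plus the ground truth of planted effects.

    DE proteins receive a ±``effect_log2`` shift (random sign) in every
    group after the first; the first listed group is the reference.
    """
    rng = _rng(config.seed, 0)
    n, m = config.n_proteins, config.n_samples
    protein_ids = [f"P{i:05d}" for i in range(n)]
    gene_symbols = [f"Gene{i:05d}" for i in range(n)]

    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n)
    effect[de_idx] = signs * config.effect_log2

    if config.sample_scale_log2 is None:
        scale = rng.normal(0.0, 0.3, size=m)
    else:
        scale = np.asarray(config.sample_scale_log2, dtype=float)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    group_of_col = np.concatenate(
        [np.full(cnt, gi) for gi, (_, cnt) in enumerate(config.groups)]
    )
    # effect applies to all non-reference groups
    effect_mat = np.outer(effect, (group_of_col > 0).astype(float))
    noise = rng.normal(0.0, config.noise_log2_sd, size=(n, m))
    log2_inten = baseline[:, None] + effect_mat + scale[None, :] + noise
    inten = np.exp2(log2_inten)

    p_missing = expit((config.mnar_midpoint_log2 - log2_inten) * config.mnar_slope)
    missing = rng.random(size=(n, m)) < p_missing

    peptides = 1 + rng.poisson(config.peptide_count_mean - 1.0, size=n)
    reverse = rng.random(n) < config.frac_reverse
    contaminant = (~reverse) & (rng.random(n) < config.frac_contaminant)

    sample_ids = list(config.design().group_of)
    matrix = LfqMatrix(
        protein_ids=protein_ids,
        gene_symbols=gene_symbols,
        peptide_counts=peptides,
        sample_ids=sample_ids,
        intensities=np.where(missing, 0.0, inten),
        missing=missing,
        reverse_flag=reverse,
        contaminant_flag=contaminant,
    )
    clean = reverse | contaminant
    truth = GroundTruth(
        de_protein_ids={protein_ids[i] for i in de_idx if not clean[i]},
        true_effect_log2={
            protein_ids[i]: float(effect[i]) for i in range(n) if not clean[i]
        },
    )
    return matrix, truth


def simulate_ppi(
    n_background: int,
    planted_cliques: list[int],
    p_background: float,
    seed: int = 0,
) -> PpiGraph:
    """Planted disjoint cliques plus Erdős–Rényi background noise.

    Clique-internal edges carry confidence 0.9; background edges a uniform
    confidence in (0.4, 1], so none are removed by the default threshold.
    """
    if any(k < 3 for k in planted_cliques):
        raise ValueError("clique sizes must be >= 3")
    if not 0.0 <= p_background < 1.0:
        raise ValueError("p_background must lie in [0, 1)")
    rng = _rng(seed, 1)
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    idx = 0
    for ci, k in enumerate(planted_cliques):
        members = [f"C{ci}_{j:02d}" for j in range(k)]
        nodes += members
        for a in range(k):
            for b in range(a + 1, k):
                edges.append((members[a], members[b], 0.9))
        idx += k
    bg = [f"B{j:04d}" for j in range(n_background)]
    nodes += bg
    for a in range(n_background):
        for b in range(a + 1, n_background):
            if rng.random() < p_background:
                edges.append((bg[a], bg[b], float(0.4 + 0.6 * rng.random())))
    ppi = graph_from_edges(edges, score_threshold=0.4)
    ppi.graph.add_nodes_from(nodes)
    return ppi


def simulate_terms(
    protein_ids: list[str],
    n_terms: int,
    genes_per_term: int,
    enriched_term_genes_from: set[str],
    seed: int = 0,
    enriched_fraction: float = 0.8,
) -> TermCatalog:
    """A term catalog with one planted enriched term.

    Term ``T0000`` draws at least ``enriched_fraction`` of its genes from
    ``enriched_term_genes_from``; the remaining terms are uniform draws from
    the universe.
    """
    if not protein_ids:
        raise ValueError("empty universe")
    if genes_per_term > len(protein_ids):
        raise ValueError("genes_per_term exceeds the universe size")
    rng = _rng(seed, 2)
    universe = list(protein_ids)
    pool = sorted(set(enriched_term_genes_from) & set(universe))
    terms = []
    n_from_pool = min(len(pool), int(np.ceil(enriched_fraction * genes_per_term)))
    planted = set(rng.choice(pool, size=n_from_pool, replace=False)) if n_from_pool else set()
    rest = [g for g in universe if g not in planted]
    extra = rng.choice(rest, size=genes_per_term - len(planted), replace=False)
    terms.append(Term("T0000", "planted_term", frozenset(planted | set(extra))))
    for ti in range(1, n_terms):
        genes = rng.choice(universe, size=genes_per_term, replace=False)
        terms.append(Term(f"T{ti:04d}", f"background_term_{ti}", frozenset(genes)))
    return TermCatalog(terms=terms, universe=frozenset(universe))


def simulate_ct(
    genes: list[str],
    groups: list[str],
    reference_gene: str,
    effects: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    baseline_delta_ct: float = 5.0,
    reference_ct: float = 18.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table: reference gene flat, targets shifted per group.

    ``effects[(gene, group)]`` is a ΔCt shift in cycles; one cycle is one
    doubling, so a −1 shift doubles the downstream fold change.
    """
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not in gene list")
    effects = effects or {}
    rng = _rng(seed, 3)
    records = []
    for group in groups:
        sample = f"{group}_s1"
        for gene in genes:
            for rep in range(1, n_replicates + 1):
                if gene == reference_gene:
                    ct = reference_ct
                else:
                    ct = (
                        reference_ct
                        + baseline_delta_ct
                        + effects.get((gene, group), 0.0)
                        + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    )
                records.append(
                    {"sample_id": sample, "group_label": group, "gene": gene,
                     "replicate_index": rep, "ct": ct}
                )
    return pd.DataFrame(records)


def write_edges(ppi: PpiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(ppi.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['combined_score']:.6g}\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_id": list(truth.true_effect_log2),
            "true_effect_log2": list(truth.true_effect_log2.values()),
            "is_de": [pid in truth.de_protein_ids for pid in truth.true_effect_log2],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False)
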