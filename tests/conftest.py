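import numpy as np
import pytest

from traplfq import (
    SimConfig,
    drop_artifacts,
    impute_noise,
    median_normalize,
    quantifiability_filter,
    simulate_lfq,
)
from traplfq.lfq_io import Design, LfqMatrix


@pytest.fixture(scope="session")
def sim_default():
    """A standard 2000-protein 4v4 simulation with planted effects."""
    cfg = SimConfig(n_proteins=2000, frac_de=0.05, effect_log2=2.0, seed=42)
    matrix, truth = simulate_lfq(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def preprocessed(sim_default):
    """The default simulation taken through artifact removal, normalization,
    imputation and the quantifiability filter."""
    cfg, matrix, truth = sim_default
    design = cfg.design()
    pre = impute_noise(median_normalize(drop_artifacts(matrix)))
    kept, dropped = quantifiability_filter(
        pre.matrix, design, ("test", "ref"),
        pre_imputation_missing=pre.pre_imputation_missing,
    )
    return cfg, design, pre, kept, dropped, truth


def tiny_matrix(intensities, missing=None, peptides=None, **kwargs):
    """Hand-rolled LfqMatrix for targeted unit tests."""
    inten = np.asarray(intensities, dtype=float)
    n, m = inten.shape
    return LfqMatrix(
        protein_ids=[f"P{i}" for i in range(n)],
        gene_symbols=[f"G{i}" for i in range(n)],
        peptide_counts=np.asarray(peptides if peptides is not None else [3] * n),
        sample_ids=[f"s{j}" for j in range(m)],
        intensities=inten,
        missing=np.zeros((n, m), bool) if missing is None else np.asarray(missing, bool),
        **kwargs,
    )


def two_group_design(n_per_group=2, groups=("A", "B")):
    group_of = {}
    for gi, g in enumerate(groups):
        for r in range(n_per_group):
            group_of[f"s{gi * n_per_group + r}"] = g
    return Design(group_of=group_of, comparisons=[(groups[1], groups[0])])
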