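"""Normalization, first-centile noise imputation, and quantifiability filtering.

The preprocessing pipeline is: per-sample median normalization of the observed
LFQ intensities, imputation of missing cells with each sample's first-centile
"noise" value, then a per-comparison quantifiability filter that requires at
least 80% observed values (on the pre-imputation mask) in one of the two
groups and at least 2 razor+unique peptides.  Medians and percentiles are
taken over observed cells only: with MaxQuant's missing-as-zero encoding,
including the zeros would drag the first centile to 0 and turn imputation
into a no-op-to-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .lfq_io import Design, LfqMatrix


class DegenerateSampleError(ValueError):
    """A sample lacks enough observed values for the requested statistic."""


@dataclass
class PreprocessedMatrix:
    """An imputed LfqMatrix plus the bookkeeping imputation left behind."""

    matrix: LfqMatrix                 # fully imputed: missing mask all False
    imputed_mask: np.ndarray          # True exactly where input was missing
    per_sample_noise_value: np.ndarray
    per_sample_median: np.ndarray
    pre_imputation_missing: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.missing.any():
            raise ValueError("preprocessed matrix must have no missing cells")
        if (self.per_sample_noise_value > self.per_sample_median).any():
            raise ValueError("noise value exceeds sample median")


def median_normalize(m: LfqMatrix) -> LfqMatrix:
    """Equalize per-sample medians of observed intensities.

    Each observed cell is divided by its sample's median and multiplied by
    the grand median of the per-sample medians, so every sample ends up with
    the same median while intensities keep their original order of magnitude.
    The operation is idempotent and invariant to per-sample scale factors.
    """
    out = m.copy()
    medians = np.empty(m.n_samples)
    for j, s in enumerate(m.sample_ids):
        obs = m.intensities[~m.missing[:, j], j]
        if obs.size == 0:
            raise DegenerateSampleError(f"sample {s!r} has no observed values")
        medians[j] = np.median(obs)
    grand = np.median(medians)
    for j in range(m.n_samples):
        col = ~m.missing[:, j]
        out.intensities[col, j] = m.intensities[col, j] * (grand / medians[j])
    return out


def impute_noise(m: LfqMatrix, centile: float = 1.0) -> PreprocessedMatrix:
    """Fill missing cells with each sample's first-centile noise value.

    The percentile uses the linear-interpolation definition over the sample's
    observed values.  Observed cells are untouched.
    """
    out = m.copy()
    noise = np.empty(m.n_samples)
    medians = np.empty(m.n_samples)
    for j, s in enumerate(m.sample_ids):
        obs = m.intensities[~m.missing[:, j], j]
        if obs.size < 2:
            raise DegenerateSampleError(
                f"sample {s!r} has {obs.size} observed values; need >= 2"
            )
        noise[j] = np.percentile(obs, centile)
        medians[j] = np.median(obs)
        col_missing = m.missing[:, j]
        out.intensities[col_missing, j] = noise[j]
    out.missing = np.zeros_like(m.missing)
    return PreprocessedMatrix(
        matrix=out,
        imputed_mask=m.missing.copy(),
        per_sample_noise_value=noise,
        per_sample_median=medians,
        pre_imputation_missing=m.missing.copy(),
    )


def _group_columns(m: LfqMatrix, design: Design, group: str) -> list[int]:
    samples = set(design.samples_in(group))
    cols = [j for j, s in enumerate(m.sample_ids) if s in samples]
    if not cols:
        raise KeyError(f"group {group!r} has no samples in the matrix")
    return cols


def quantifiability_filter(
    m: LfqMatrix,
    design: Design,
    comparison: tuple[str, str],
    pre_imputation_missing: np.ndarray | None = None,
    min_frac: float = 0.8,
    min_peptides: int = 2,
) -> tuple[list[str], list[str]]:
    """Split protein ids into (kept, dropped) for one two-group comparison.

    A protein is kept iff its observed fraction — computed on the
    pre-imputation mask — is at least ``min_frac`` in at least one of the two
    groups, AND it has at least ``min_peptides`` razor+unique peptides.  The
    fraction comparison is exact rational arithmetic, so 3 observed out of 4
    never sneaks past 0.8 through float rounding.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    missing = m.missing if pre_imputation_missing is None else pre_imputation_missing
    test, ref = comparison
    cols_a = _group_columns(m, design, test)
    cols_b = _group_columns(m, design, ref)
    frac_cut = Fraction(str(min_frac))
    kept, dropped = [], []
    for i, pid in enumerate(m.protein_ids):
        obs_a = int((~missing[i, cols_a]).sum())
        obs_b = int((~missing[i, cols_b]).sum())
        frac_ok = (
            Fraction(obs_a, len(cols_a)) >= frac_cut
            or Fraction(obs_b, len(cols_b)) >= frac_cut
        )
        if frac_ok and m.peptide_counts[i] >= min_peptides:
            kept.append(pid)
        else:
            dropped.append(pid)
    return kept, dropped


def preprocessing_report(pre: PreprocessedMatrix) -> pd.DataFrame:
    """Per-sample summary: median, noise value, number of imputed cells."""
    return pd.DataFrame(
        {
            "sample_id": pre.matrix.sample_ids,
            "median": pre.per_sample_median,
            "noise_value": pre.per_sample_noise_value,
            "n_imputed": pre.imputed_mask.sum(axis=0),
        }
    )


def write_preprocessing_report(pre: PreprocessedMatrix, path: str | Path) -> None:
    preprocessing_report(pre).to_csv(path, sep="\t", index=False)
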