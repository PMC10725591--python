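"""Reading and writing MaxQuant-style ``proteinGroups`` tables.

The on-disk dialect is the tab-delimited ``proteinGroups.txt`` that MaxQuant
emits: one row per protein group, one ``LFQ intensity <sample>`` column per
sample, peptide counts in ``Peptide counts (razor+unique)``, and ``+`` markers
in the ``Reverse`` / ``Potential contaminant`` columns.  A zero LFQ cell means
"not quantified"; in memory that becomes an explicit boolean missing mask so
that filters defined on the pre-imputation data stay well-defined after
imputation has filled the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LFQ_PREFIX = "LFQ intensity "

PROTEIN_ID_COL = "Protein IDs"
GENE_COL = "Gene names"
PEPTIDE_COL = "Peptide counts (razor+unique)"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"


class FormatError(ValueError):
    """The file does not follow the expected proteinGroups dialect."""


@dataclass
class LfqMatrix:
    """Protein × sample LFQ intensity matrix with an explicit missing mask.

    Attributes
    ----------
    protein_ids : list of accession strings, one per row.
    gene_symbols : list of gene names (may contain empty strings).
    peptide_counts : (n_proteins,) int array of razor+unique peptide counts.
    sample_ids : ordered list of sample names.
    intensities : (n_proteins, n_samples) float array, linear scale.
        Values at masked positions are undefined (stored as 0).
    missing : boolean array, True where the cell was not quantified.
    reverse_flag, contaminant_flag : per-protein booleans.
    """

    protein_ids: list[str]
    gene_symbols: list[str]
    peptide_counts: np.ndarray
    sample_ids: list[str]
    intensities: np.ndarray
    missing: np.ndarray
    reverse_flag: np.ndarray = field(default=None)  # type: ignore[assignment]
    contaminant_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n, m = len(self.protein_ids), len(self.sample_ids)
        self.peptide_counts = np.asarray(self.peptide_counts, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.reverse_flag is None:
            self.reverse_flag = np.zeros(n, dtype=bool)
        if self.contaminant_flag is None:
            self.contaminant_flag = np.zeros(n, dtype=bool)
        self.reverse_flag = np.asarray(self.reverse_flag, dtype=bool)
        self.contaminant_flag = np.asarray(self.contaminant_flag, dtype=bool)
        if not self.gene_symbols:
            self.gene_symbols = [""] * n
        if self.intensities.shape != (n, m):
            raise ValueError(
                f"intensity shape {self.intensities.shape} != ({n}, {m})"
            )
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape mismatch")
        if len(self.peptide_counts) != n:
            raise ValueError("peptide_counts length mismatch")
        observed = self.intensities[~self.missing]
        if observed.size and (observed < 0).any():
            raise ValueError("observed intensities must be non-negative")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "LfqMatrix":
        return replace(
            self,
            protein_ids=list(self.protein_ids),
            gene_symbols=list(self.gene_symbols),
            peptide_counts=self.peptide_counts.copy(),
            sample_ids=list(self.sample_ids),
            intensities=self.intensities.copy(),
            missing=self.missing.copy(),
            reverse_flag=self.reverse_flag.copy(),
            contaminant_flag=self.contaminant_flag.copy(),
        )

    def take_rows(self, idx: np.ndarray) -> "LfqMatrix":
        """New matrix with only the rows at ``idx``, order preserved."""
        idx = np.asarray(idx)
        return replace(
            self,
            protein_ids=[self.protein_ids[i] for i in idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            peptide_counts=self.peptide_counts[idx],
            intensities=self.intensities[idx],
            missing=self.missing[idx],
            reverse_flag=self.reverse_flag[idx],
            contaminant_flag=self.contaminant_flag[idx],
        )


@dataclass
class Design:
    """Sample→group assignment plus the ordered comparisons to run.

    ``comparisons`` is a list of (test_group, reference_group) pairs; the
    ratio reported downstream is test over reference.
    """

    group_of: dict[str, str]
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def samples_in(self, group: str) -> list[str]:
        hits = [s for s, g in self.group_of.items() if g == group]
        if not hits:
            raise KeyError(f"no samples assigned to group {group!r}")
        return hits

    def validate_against(self, m: LfqMatrix) -> None:
        unknown = [s for s in m.sample_ids if s not in self.group_of]
        if unknown:
            raise ValueError(f"samples without a group: {unknown}")
        groups = set(self.group_of.values())
        for test, ref in self.comparisons:
            if test == ref:
                raise ValueError(f"comparison {test}:{ref} is degenerate")
            for g in (test, ref):
                if g not in groups:
                    raise ValueError(f"comparison references unknown group {g!r}")


def read_protein_groups(path: str | Path, lfq_column_prefix: str = LFQ_PREFIX) -> LfqMatrix:
    """Parse a proteinGroups-dialect TSV into an :class:`LfqMatrix`.

    Zero intensities are recorded as missing (the MaxQuant convention);
    ``+`` in the Reverse / Potential contaminant columns sets the per-row
    flags but no rows are removed here — see :func:`drop_artifacts`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    lfq_cols = [c for c in df.columns if c.startswith(lfq_column_prefix)]
    if not lfq_cols:
        raise FormatError(
            f"{path}: no columns start with {lfq_column_prefix!r}"
        )
    sample_ids = [c[len(lfq_column_prefix):] for c in lfq_cols]
    try:
        inten = df[lfq_cols].astype(float).to_numpy()
    except ValueError as exc:
        # re-scan to name the offending cell
        for c in lfq_cols:
            for i, v in enumerate(df[c]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric intensity {v!r} at row {i}, column {c!r}"
                    ) from exc
        raise
    missing = inten == 0.0

    def plus_flags(col: str) -> np.ndarray:
        if col not in df.columns:
            return np.zeros(len(df), dtype=bool)
        return df[col].fillna("").str.strip().eq("+").to_numpy()

    peptides = (
        pd.to_numeric(df[PEPTIDE_COL], errors="coerce").fillna(0).astype(int).to_numpy()
        if PEPTIDE_COL in df.columns
        else np.zeros(len(df), dtype=int)
    )
    genes = (
        df[GENE_COL].fillna("").tolist() if GENE_COL in df.columns else [""] * len(df)
    )
    if PROTEIN_ID_COL not in df.columns:
        raise FormatError(f"{path}: missing column {PROTEIN_ID_COL!r}")
    return LfqMatrix(
        protein_ids=df[PROTEIN_ID_COL].astype(str).tolist(),
        gene_symbols=genes,
        peptide_counts=peptides,
        sample_ids=sample_ids,
        intensities=np.where(missing, 0.0, inten),
        missing=missing,
        reverse_flag=plus_flags(REVERSE_COL),
        contaminant_flag=plus_flags(CONTAMINANT_COL),
    )


def write_protein_groups(m: LfqMatrix, path: str | Path,
                         lfq_column_prefix: str = LFQ_PREFIX) -> None:
    """Write an LfqMatrix back to the proteinGroups dialect (missing = 0)."""
    data: dict[str, object] = {
        PROTEIN_ID_COL: m.protein_ids,
        GENE_COL: m.gene_symbols,
        PEPTIDE_COL: m.peptide_counts,
        REVERSE_COL: np.where(m.reverse_flag, "+", ""),
        CONTAMINANT_COL: np.where(m.contaminant_flag, "+", ""),
    }
    for j, s in enumerate(m.sample_ids):
        col = np.where(m.missing[:, j], 0.0, m.intensities[:, j])
        data[f"{lfq_column_prefix}{s}"] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def drop_artifacts(m: LfqMatrix) -> LfqMatrix:
    """Remove decoy (Reverse) and contaminant rows; everything else untouched."""
    keep = ~(m.reverse_flag | m.contaminant_flag)
    return m.take_rows(np.flatnonzero(keep))


def read_design(design_path: str | Path,
                comparisons_path: str | Path | None = None) -> Design:
    """Read a 2-column sample→group TSV and an optional test/ref comparison TSV."""
    df = pd.read_csv(design_path, sep="\t", header=None,
                     names=["sample_id", "group_label"], dtype=str, comment="#")
    design = Design(group_of=dict(zip(df.sample_id, df.group_label)))
    if comparisons_path is not None:
        cf = pd.read_csv(comparisons_path, sep="\t", header=None,
                         names=["test", "ref"], dtype=str, comment="#")
        design.comparisons = list(zip(cf.test, cf.ref))
    return design


def write_design(design: Design, design_path: str | Path,
                 comparisons_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {"sample_id": list(design.group_of), "group_label": list(design.group_of.values())}
    ).to_csv(design_path, sep="\t", index=False, header=False)
    if comparisons_path is not None and design.comparisons:
        pd.DataFrame(design.comparisons).to_csv(
            comparisons_path, sep="\t", index=False, header=False
        )
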