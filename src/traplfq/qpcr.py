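"""Relative expression from qPCR cycle thresholds: ΔCt and ΔΔCt methods.

A lower Ct means earlier detection and hence higher expression; one cycle is
one doubling.  The implementation follows the Livak convention,
``relative expression = 2^(-ΔCt)`` and ``fold = 2^(-ΔΔCt)``; the
``literal_sign`` flag uses the unsigned exponent (2^ΔCt / 2^ΔΔCt) instead,
which inverts every result.  Undetermined ("UD") target reactions propagate
an undetermined result and are excluded listwise from group means with an
explicit exclusion count; they are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UD = "UD"


class UndeterminedReferenceError(ValueError):
    """The reference gene itself is undetermined for a sample."""


@dataclass
class CtTable:
    """Long-format cycle-threshold records plus the quantification anchors."""

    records: pd.DataFrame  # sample_id, group_label, gene, replicate_index, ct
    reference_gene: str
    calibrator_group: str | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "group_label", "gene", "replicate_index", "ct"}
        missing_cols = required - set(self.records.columns)
        if missing_cols:
            raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
        if self.reference_gene not in set(self.records["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent from table")


def _ct_value(v) -> float | None:
    """None for undetermined, else the Ct in cycles (> 0 enforced)."""
    if isinstance(v, str) and v.strip().upper() == UD:
        return None
    ct = float(v)
    if np.isnan(ct):
        return None
    if ct <= 0:
        raise ValueError(f"Ct must be positive, got {ct}")
    return ct


def read_ct_table(path: str | Path, reference_gene: str,
                  calibrator_group: str | None = None) -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype={"ct": str})
    return CtTable(records=df, reference_gene=reference_gene,
                   calibrator_group=calibrator_group)


def _mean_ct(sub: pd.DataFrame) -> tuple[float | None, int]:
    """Mean determined Ct over technical replicates and the count of UD ones."""
    values = [_ct_value(v) for v in sub["ct"]]
    determined = [v for v in values if v is not None]
    n_ud = len(values) - len(determined)
    if not determined:
        return None, n_ud
    return float(np.mean(determined)), n_ud


def delta_ct(table: CtTable, literal_sign: bool = False) -> pd.DataFrame:
    """Per (sample, gene) ΔCt and relative expression 2^(−ΔCt).

    Technical replicates are averaged on the Ct scale before
    exponentiation.  Undetermined targets yield an undetermined row
    (expression NaN, ``undetermined`` True).
    """
    df = table.records
    rows = []
    for sample, sub in df.groupby("sample_id", sort=True):
        ref_ct, _ = _mean_ct(sub[sub["gene"] == table.reference_gene])
        targets = sub[sub["gene"] != table.reference_gene]
        if ref_ct is None and not targets.empty:
            raise UndeterminedReferenceError(
                f"reference gene undetermined for sample {sample!r}"
            )
        for gene, gsub in targets.groupby("gene", sort=True):
            ct, n_ud = _mean_ct(gsub)
            group = gsub["group_label"].iloc[0]
            if ct is None:
                rows.append({"sample_id": sample, "group_label": group,
                             "gene": gene, "delta_ct": np.nan,
                             "rel_expr": np.nan, "undetermined": True,
                             "n_ud_replicates": n_ud})
                continue
            dct = ct - ref_ct
            expo = dct if literal_sign else -dct
            rows.append({"sample_id": sample, "group_label": group,
                         "gene": gene, "delta_ct": dct,
                         "rel_expr": float(2.0 ** expo), "undetermined": False,
                         "n_ud_replicates": n_ud})
    return pd.DataFrame(rows)


def delta_delta_ct(table: CtTable, calibrator_group: str | None = None,
                   literal_sign: bool = False) -> pd.DataFrame:
    """Per (group, gene) fold change vs the calibrator group, 2^(−ΔΔCt).

    The ΔΔCt is the difference of group-mean ΔCt values; the replicate
    standard deviation of ΔCt in the test group propagates to the interval
    ``2^(−ΔΔCt ± SD)`` reported as fold_lo / fold_hi.
    """
    calibrator = calibrator_group or table.calibrator_group
    if calibrator is None:
        raise ValueError("no calibrator group given")
    per_sample = delta_ct(table)
    per_sample = per_sample[~per_sample["undetermined"]]
    rows = []
    for gene, gsub in per_sample.groupby("gene", sort=True):
        cal = gsub[gsub["group_label"] == calibrator]["delta_ct"]
        if cal.empty:
            raise ValueError(
                f"calibrator group {calibrator!r} has no determined ΔCt for {gene!r}"
            )
        cal_mean = float(cal.mean())
        for group, sub in gsub.groupby("group_label", sort=True):
            ddct = float(sub["delta_ct"].mean()) - cal_mean
            sd = float(sub["delta_ct"].std(ddof=1)) if len(sub) > 1 else 0.0
            sign = 1.0 if literal_sign else -1.0
            fold = 2.0 ** (sign * ddct)
            lo, hi = sorted([2.0 ** (sign * (ddct + sd)), 2.0 ** (sign * (ddct - sd))])
            rows.append({"group_label": group, "gene": gene,
                         "delta_delta_ct": ddct, "fold": fold,
                         "fold_lo": lo, "fold_hi": hi, "n_samples": len(sub)})
    return pd.DataFrame(rows)


def ddct_from_replicates(table: CtTable, calibrator_group: str | None = None,
                         literal_sign: bool = False) -> pd.DataFrame:
    """ΔΔCt where technical replicates of one sample act as the unit.

    Used when each group is represented by a single pooled sample: replicate
    ΔCt values (target replicate minus mean reference Ct) supply the SD that
    propagates into the fold interval.
    """
    calibrator = calibrator_group or table.calibrator_group
    if calibrator is None:
        raise ValueError("no calibrator group given")
    df = table.records
    rows = []
    rep_dcts: dict[tuple[str, str], np.ndarray] = {}
    for (group, gene), sub in df[df["gene"] != table.reference_gene].groupby(
        ["group_label", "gene"], sort=True
    ):
        sample_ids = sub["sample_id"].unique()
        dcts = []
        for sid in sample_ids:
            ref = df[(df["sample_id"] == sid) & (df["gene"] == table.reference_gene)]
            ref_ct, _ = _mean_ct(ref)
            if ref_ct is None:
                raise UndeterminedReferenceError(
                    f"reference gene undetermined for sample {sid!r}"
                )
            for v in sub[sub["sample_id"] == sid]["ct"]:
                ct = _ct_value(v)
                if ct is not None:
                    dcts.append(ct - ref_ct)
        rep_dcts[(group, gene)] = np.asarray(dcts)
    genes = sorted({g for _, g in rep_dcts})
    for gene in genes:
        key_cal = (calibrator, gene)
        if key_cal not in rep_dcts or rep_dcts[key_cal].size == 0:
            raise ValueError(
                f"calibrator group {calibrator!r} has no determined ΔCt for {gene!r}"
            )
        cal_mean = float(rep_dcts[key_cal].mean())
        for (group, g), dcts in sorted(rep_dcts.items()):
            if g != gene or dcts.size == 0:
                continue
            ddct = float(dcts.mean()) - cal_mean
            sd = float(dcts.std(ddof=1)) if dcts.size > 1 else 0.0
            sign = 1.0 if literal_sign else -1.0
            fold = 2.0 ** (sign * ddct)
            lo, hi = sorted([2.0 ** (sign * (ddct + sd)), 2.0 ** (sign * (ddct - sd))])
            rows.append({"group_label": group, "gene": gene,
                         "delta_delta_ct": ddct, "fold": fold,
                         "fold_lo": lo, "fold_hi": hi, "n_replicates": int(dcts.size)})
    return pd.DataFrame(rows)
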