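"""Differential expression: group ratios, z-scores, moderated t, BH, DEP calls.

Two statistics are computed per quantifiable protein:

* a standardized log2 group ratio ``z = (x - mu) / sigma`` where
  ``x = log2(mean_test / mean_ref)`` on linear post-imputation intensities and
  ``mu``, ``sigma`` are the mean and (n-1) standard deviation of x over all
  quantifiable proteins — a data-centering device, not a test;
* an empirical-Bayes moderated t on log2 intensities, whose per-protein
  variance is shrunk toward a prior (d0, s0^2) estimated by moment-matching
  the marginal distribution of log s_g^2 (digamma/trigamma method).

A protein is called differentially expressed when BH q < q_cut AND
|z| > z_cut — both gates, not either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .lfq_io import Design
from .preprocess import PreprocessedMatrix, _group_columns


class DegenerateDataError(ValueError):
    """All ratios identical (sigma = 0) or all residual variances zero."""


@dataclass
class EBayesFit:
    """Empirical-Bayes variance prior and per-protein components.

    ``d0`` may be ``math.inf``, in which case every moderated variance equals
    ``s0_sq`` and the reference distribution is Normal.
    """

    d0: float
    s0_sq: float
    s_g_sq: np.ndarray
    d_g: int

    def moderated_var(self) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(self.s_g_sq, self.s0_sq)
        if self.d0 == 0:
            return self.s_g_sq.copy()
        return (self.d0 * self.s0_sq + self.d_g * self.s_g_sq) / (self.d0 + self.d_g)


def _rows_for(pre: PreprocessedMatrix, kept_ids: list[str]) -> np.ndarray:
    index = {pid: i for i, pid in enumerate(pre.matrix.protein_ids)}
    try:
        return np.array([index[pid] for pid in kept_ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"kept id not in matrix: {exc.args[0]!r}") from exc


def group_ratio_z(
    pre: PreprocessedMatrix,
    design: Design,
    comparison: tuple[str, str],
    kept_ids: list[str],
    ddof: int = 1,
) -> pd.DataFrame:
    """Linear-scale group means, ratio, x = log2(ratio) and the z-score.

    ``ddof=1`` (sample standard deviation) is the default convention for
    sigma; pass ``ddof=0`` for the population definition.
    """
    if not kept_ids:
        raise ValueError("kept_ids is empty")
    test, ref = comparison
    m = pre.matrix
    rows = _rows_for(pre, kept_ids)
    cols_t = _group_columns(m, design, test)
    cols_r = _group_columns(m, design, ref)
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError("both groups need >= 2 samples")
    mean_t = m.intensities[np.ix_(rows, cols_t)].mean(axis=1)
    mean_r = m.intensities[np.ix_(rows, cols_r)].mean(axis=1)
    ratio = mean_t / mean_r
    x = np.log2(ratio)
    sigma = x.std(ddof=ddof)
    if sigma == 0:
        raise DegenerateDataError("all log2 ratios identical; sigma = 0")
    z = (x - x.mean()) / sigma
    imput = pre.imputed_mask
    return pd.DataFrame(
        {
            "protein_id": kept_ids,
            "gene": [m.gene_symbols[i] for i in rows],
            "mean_test": mean_t,
            "mean_ref": mean_r,
            "ratio": ratio,
            "log2_ratio": x,
            "z": z,
            "n_imputed_test": imput[np.ix_(rows, cols_t)].sum(axis=1),
            "n_imputed_ref": imput[np.ix_(rows, cols_r)].sum(axis=1),
        }
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x approximation
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s_g_sq: np.ndarray, d_g: int) -> tuple[float, float]:
    """Estimate (d0, s0^2) from per-protein pooled variances.

    Moment-matching on ``e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2)``:
    under the scaled-chi-square model, var(e) = trigamma(d_g/2) +
    trigamma(d0/2), so d0 comes from inverting the trigamma function and
    s0^2 from the mean of e.  When the empirical var(e) does not exceed
    trigamma(d_g/2) there is no evidence of variance heterogeneity and the
    fit degenerates gracefully to d0 = infinity.
    """
    positive = s_g_sq[s_g_sq > 0]
    if positive.size == 0:
        raise DegenerateDataError(
            "all residual variances are zero; data look constant within groups"
        )
    e = np.log(positive) - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    )
    return d0, float(s0_sq)


def ebayes_moderated_t(
    pre: PreprocessedMatrix,
    design: Design,
    comparison: tuple[str, str],
    kept_ids: list[str],
    d0_override: float | None = None,
) -> tuple[EBayesFit, np.ndarray, np.ndarray]:
    """Moderated two-sample t on log2 intensities.

    Returns the fitted prior and per-protein (t_mod, p).  ``d0_override``
    forces the prior degrees of freedom: 0 reproduces the ordinary
    equal-variance t, ``math.inf`` the pooled z-statistic.
    """
    test, ref = comparison
    m = pre.matrix
    rows = _rows_for(pre, kept_ids)
    cols_t = _group_columns(m, design, test)
    cols_r = _group_columns(m, design, ref)
    n1, n2 = len(cols_t), len(cols_r)
    d_g = n1 + n2 - 2
    if d_g < 1:
        raise ValueError("need n1 + n2 - 2 >= 1 residual degrees of freedom")
    log_t = np.log2(m.intensities[np.ix_(rows, cols_t)])
    log_r = np.log2(m.intensities[np.ix_(rows, cols_r)])
    diff = log_t.mean(axis=1) - log_r.mean(axis=1)
    ss = log_t.var(axis=1, ddof=1) * (n1 - 1) + log_r.var(axis=1, ddof=1) * (n2 - 1)
    s_g_sq = ss / d_g
    if d0_override is not None:
        d0 = float(d0_override)
        if math.isinf(d0):
            _, s0_sq = fit_variance_prior(s_g_sq, d_g)
        else:
            s0_sq = float(s_g_sq[s_g_sq > 0].mean()) if (s_g_sq > 0).any() else 0.0
    else:
        d0, s0_sq = fit_variance_prior(s_g_sq, d_g)
    fit = EBayesFit(d0=d0, s0_sq=s0_sq, s_g_sq=s_g_sq, d_g=d_g)
    s_tilde_sq = fit.moderated_var()
    if (s_tilde_sq == 0).all():
        raise DegenerateDataError(
            "all moderated variances are zero; add jitter or check for constant data"
        )
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / se
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=d0 + d_g)
    return fit, t_mod, p


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deps(table: pd.DataFrame, q_cut: float = 0.05, z_cut: float = 1.96) -> pd.DataFrame:
    """Attach the dual-threshold call: up/down iff q < q_cut and |z| > z_cut."""
    out = table.copy()
    sig = out["q"] < q_cut
    out["call"] = np.where(
        sig & (out["z"] > z_cut), "up", np.where(sig & (out["z"] < -z_cut), "down", "ns")
    )
    out.attrs["n_up"] = int((out["call"] == "up").sum())
    out.attrs["n_down"] = int((out["call"] == "down").sum())
    return out


def dep_table(
    pre: PreprocessedMatrix,
    design: Design,
    comparison: tuple[str, str],
    kept_ids: list[str],
    q_cut: float = 0.05,
    z_cut: float = 1.96,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Full DEP table for one comparison: ratio/z path + moderated t + calls."""
    table = group_ratio_z(pre, design, comparison, kept_ids)
    fit, t_mod, p = ebayes_moderated_t(
        pre, design, comparison, kept_ids, d0_override=d0_override
    )
    table["t_mod"] = t_mod
    table["p"] = p
    table["q"] = bh_adjust(p)
    table = call_deps(table, q_cut=q_cut, z_cut=z_cut)
    table.attrs["ebayes_d0"] = fit.d0
    table.attrs["ebayes_s0_sq"] = fit.s0_sq
    cols = [
        "protein_id", "gene", "mean_test", "mean_ref", "ratio", "log2_ratio",
        "z", "t_mod", "p", "q", "call", "n_imputed_test", "n_imputed_ref",
    ]
    return table[cols]
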