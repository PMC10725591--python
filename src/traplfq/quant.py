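"""Quantitative utilities: transgene detectability and targeted-metabolomics
normalization/calibration.

The detectability estimate answers whether a tagged ribosomal fusion protein
expressed in cortical microglia could ever show up on a western blot: count
the microglia in half a cortex, multiply by copies per cell, convert to moles
and then to picograms via the molar mass.  The printed value of Avogadro's
number (6.023e23) is the default so the arithmetic reproduces the published
figures digit for digit; the CODATA value is available as
``AVOGADRO_CODATA``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

AVOGADRO_PRINTED = 6.023e23
AVOGADRO_CODATA = 6.02214076e23


@dataclass
class DetectabilityInput:
    total_microglia: float = 3.5e6
    hemisphere_divisor: float = 2.0
    cortical_fraction: float = 0.05
    copies_per_cell: float = 100.0
    avogadro: float = AVOGADRO_PRINTED
    molar_mass: float = 53_000.0

    def __post_init__(self) -> None:
        values = [self.total_microglia, self.hemisphere_divisor,
                  self.copies_per_cell, self.avogadro, self.molar_mass]
        if any(v <= 0 for v in values):
            raise ValueError("all detectability inputs must be strictly positive")
        if not 0.0 < self.cortical_fraction < 1.0:
            raise ValueError("cortical_fraction must lie in (0, 1)")


@dataclass
class DetectabilityResult:
    cells: float
    moles: float
    mass_pg: float          # unrounded
    mass_pg_rounded: float  # reported to 1 decimal


def detectability(inp: DetectabilityInput = DetectabilityInput()) -> DetectabilityResult:
    """Cells in half a cortex, moles of fusion protein, and mass in pg."""
    cells = inp.total_microglia / inp.hemisphere_divisor * inp.cortical_fraction
    moles = cells * inp.copies_per_cell / inp.avogadro
    mass_g = moles * inp.molar_mass
    mass_pg = mass_g * 1e12
    return DetectabilityResult(
        cells=cells, moles=moles, mass_pg=mass_pg,
        mass_pg_rounded=round(mass_pg, 1),
    )


def normalize_peak_areas(
    analyte_areas: np.ndarray | list[float],
    internal_standard_areas: np.ndarray | list[float],
) -> np.ndarray:
    """Divide raw analyte areas by the mean internal-standard area (per sample)."""
    analyte = np.asarray(analyte_areas, dtype=float)
    is_areas = np.asarray(internal_standard_areas, dtype=float)
    if is_areas.size == 0:
        raise ValueError("need at least one internal-standard area")
    denom = is_areas.mean()
    if denom == 0:
        raise ValueError("mean internal-standard area is zero")
    return analyte / denom


def serial_dilution_curve(
    top_concentration: float, n_points: int, dilution_factor: float = 2.0
) -> np.ndarray:
    """Concentration ladder top/f^i for i = 0..n_points-1 (descending)."""
    if n_points < 2:
        raise ValueError("need at least 2 calibration points")
    return top_concentration / dilution_factor ** np.arange(n_points)


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float


def fit_calibration(
    concentrations: np.ndarray | list[float], responses: np.ndarray | list[float]
) -> CalibrationFit:
    """Unweighted ordinary least squares of response on concentration."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < 2 or np.all(conc == conc[0]):
        raise ValueError("calibration needs >= 2 distinct concentrations")
    if not np.isfinite(resp).all():
        raise ValueError("responses must be finite")
    res = stats.linregress(conc, resp)
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        conc_min=float(conc.min()), conc_max=float(conc.max()),
    )


def quantify(
    response: float | np.ndarray, fit: CalibrationFit
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-predict concentration(s); flags extrapolation beyond the ladder.

    Returns (concentration, extrapolated) arrays of matching shape.
    """
    if fit.slope == 0:
        raise ValueError("flat calibration; cannot invert")
    resp = np.atleast_1d(np.asarray(response, dtype=float))
    conc = (resp - fit.intercept) / fit.slope
    extrapolated = (conc < fit.conc_min) | (conc > fit.conc_max)
    return conc, extrapolated
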