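"""Back-of-envelope transgene detectability and a serial-dilution calibration.

First: how much tagged ribosomal fusion protein do the microglia of half a
cortex hold?  (3.5e6 microglia per brain, half, 5% cortical fraction,
100 copies/cell, 53 kDa.)  Second: a 10-point 2x dilution ladder fitted by
ordinary least squares with inverse prediction of an unknown.
"""

import numpy as np

from traplfq import (
    detectability, serial_dilution_curve, fit_calibration, quantify,
    normalize_peak_areas,
)

res = detectability()
print(f"microglia in half a cortex: {res.cells:,.0f}")
print(f"fusion protein: {res.moles:.3g} mol = {res.mass_pg_rounded} pg")
# ~0.8 pg is far below western-blot sensitivity, motivating mass spectrometry.

ladder = serial_dilution_curve(100.0, 10, 2.0)   # 100 mM down to 0.195 mM
responses = 2.5 * ladder + 0.3                   # noiseless detector
fit = fit_calibration(ladder, responses)
unknown, extrapolated = quantify(2.5 * 12.0 + 0.3, fit)
print(f"ladder: {ladder[0]} .. {ladder[-1]:.7f} mM, r^2 = {fit.r_squared:.6f}")
print(f"unknown back-calculated: {unknown[0]:.6f} mM (extrapolated: {extrapolated[0]})")

print("normalized area:", normalize_peak_areas([6.0], [2.0, 4.0])[0])
# analyte area divided by the mean internal-standard area: 6 / 3 = 2
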