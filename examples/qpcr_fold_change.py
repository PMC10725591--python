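"""Relative qPCR quantification: a planted -1.585-cycle shift is a 3.0-fold change.

Simulates cycle thresholds for a target gene and a flat reference gene in a
calibrator and a treated group, then recovers the fold change with the
2^(-ddCt) method; the replicate SD propagates to a fold interval.
"""

from traplfq import simulate_ct, ddct_from_replicates
from traplfq.qpcr import CtTable

ct = simulate_ct(
    ["Gapdh", "Hexb"], ["cal", "trt"], "Gapdh",
    effects={("Hexb", "trt"): -1.585},   # one cycle = one doubling
    noise_sd=0.2, n_replicates=3, seed=2,
)
table = CtTable(records=ct, reference_gene="Gapdh", calibrator_group="cal")
out = ddct_from_replicates(table)
print(out.to_string(index=False))
# The treated group's fold should be near 2^1.585 = 3.0; the calibrator's is
# exactly 1 by self-normalization.  fold_lo/fold_hi span 2^(-ddCt +/- SD).
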