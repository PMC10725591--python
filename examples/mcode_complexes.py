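"""Find dense complexes in a confidence-thresholded interaction network.

Plants a 6-clique in a 40-node sparse background, keeps edges with combined
score > 0.4, and runs MCODE (degree cutoff 2, node score cutoff 0.2,
haircut, no fluff).  The planted clique should surface as the top complex.
"""

from traplfq import simulate_ppi, mcode_complexes
from traplfq.netcluster import complexes_table

ppi = simulate_ppi(n_background=40, planted_cliques=[6], p_background=0.03, seed=5)
complexes = mcode_complexes(ppi)

print(complexes_table(complexes).to_string(index=False))
# rank 1 should be the 6 planted nodes with density 1.0 and score 6.0
# (score = density x size); background nodes form lower-ranked complexes
# only when the random edges happen to make a dense pocket.
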