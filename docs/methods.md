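# Methods

## Data model and preprocessing

LFQ intensities arrive as a MaxQuant-dialect `proteinGroups` table in which
0 means "not quantified". In memory the matrix carries an explicit boolean
missing mask, so every rule defined "before missing value imputation" stays
well-defined after imputation has filled the matrix. Decoy (`Reverse`) and
contaminant rows are removed by default before statistics; parsing itself
never drops rows.

Preprocessing runs normalize → impute → filter:

1. **Median normalization.** Each observed cell is divided by its sample's
   median of observed values and multiplied by the grand median of the
   per-sample medians, so all samples end with equal medians while
   intensities keep their physical magnitude. Medians are taken over
   observed cells only — including missing-as-zero cells would drag both
   the median and the first centile toward 0 and defeat imputation. The
   operation is idempotent, and a per-sample scale distortion is undone
   exactly whenever the distorted sample does not itself own the grand
   median (the restoration factor follows the owner; downstream ratios are
   scale-invariant either way).
2. **First-centile imputation.** Every missing cell in sample *s* receives
   the 1st percentile (linear interpolation between order statistics; the
   centile is configurable) of *s*'s observed values, computed after
   normalization, following the narrative order of the procedure. This is a
   deliberate noise-floor model: a cell is missing mostly because the
   protein sat below the detection limit.
3. **Quantifiability filter.** A protein enters a two-group comparison iff
   its observed fraction — on the pre-imputation mask — reaches 80% in at
   least one group AND it has ≥ 2 razor+unique peptides. The fraction test
   uses exact rational arithmetic (`Fraction`), so 3/4 never passes 0.8
   through float rounding. In a 4 vs 4 design the 80% rule therefore means
   "all 4 samples of one group".

## Differential expression

Two statistics are computed per kept protein, exactly as the procedure
reads:

* The **ratio/z path** works on linear post-imputation intensities:
  ratio = mean_test/mean_ref, *x* = log2 ratio, *z* = (*x* − *μ*)/*σ*. *σ*
  is the sample (n−1) standard deviation by default (configurable to the
  population definition); with this convention mean(*z*) = 0 and
  sd(*z*) = 1 hold to 1e−9 by construction. The z-score is a centering
  device — an effect-size gate — not a test.
* The **moderated t** works on log2 intensities. Per-protein pooled
  variances *s*²_g with *d*_g = n₁+n₂−2 residual df are shrunk toward a
  prior (*d*₀, *s*₀²) fitted by moment-matching
  *e*_g = log *s*²_g − ψ(*d*_g/2) + log(*d*_g/2): the excess of var(*e*)
  over ψ′(*d*_g/2) equals ψ′(*d*₀/2), inverted by a monotone Newton
  iteration (tolerance 1e−8); when the excess is non-positive the fit
  degrades gracefully to *d*₀ = ∞ (pure pooling, Normal reference).
  Proteins with *s*²_g = 0 are excluded from the moment fit but still
  shrunk by the formula; if every variance is zero the data are flagged as
  constant instead of producing spurious certainties. The implementation
  agrees with the Bioconductor reference implementation of this estimator
  to ~1e−9 on shared inputs (cross-checked in the test suite), and reduces
  to the classical equal-variance t at *d*₀ = 0 and to a pooled z at
  *d*₀ = ∞.

BH adjustment uses the step-up cumulative-minimum formulation (tie-safe);
the dual call is up/down iff q < 0.05 AND |z| > 1.96, both strict.

## Enrichment and term grouping

For a query of *n* analyzed genes against a term with *K* of *N* universe
genes and overlap *k*, the two-sided p doubles the smaller of the inclusive
tails P(X ≥ k), P(X ≤ k) of Hypergeometric(N, K, n), capped at 1. The
direction is "depleted" when *k* lies strictly below the expectation
*nK/N* and "enriched" otherwise (ties at the mean count as enriched). BH is
applied across all tested terms of one catalog per query. Terms carrying a
GO-style level outside [3, 8] are excluded before testing; unlevelled terms
pass through.

Kappa between two terms is Cohen's chance-corrected agreement of their
membership indicators over the analyzed universe (not the whole genome).
The degenerate case p_e = 1 returns 1 when agreement is perfect and 0 (with
a warning) otherwise. Significant terms are grouped as connected components
of the κ ≥ 0.4 graph; a subsequent fixed-point merge of groups sharing a
member-set Jaccard ≥ 0.5 is retained for interface completeness, though
components are already disjoint so it cannot fire — the design accepts this
redundancy in exchange for matching the documented two-stage description.
The leading term maximizes |term ∩ query|/|term|, ties broken by smaller q
then lexicographic id, making the grouping independent of input order.

## Network complexes

Edge lists are STRING-export style (node1, node2, combined_score); only
edges with score **strictly** above 0.4 are kept, isolates are retained in
the node set but excluded from outputs (counted in the summary). MCODE
weights a vertex by k × density of the highest k-core of its closed
neighborhood (0 below the degree cutoff of 2), seeds complexes in
descending weight with lexicographic tie-break, admits neighbors with
weight ≥ 0.8 × seed weight (node score cutoff 0.2), keeps complexes
node-disjoint via visited-set semantics, haircuts singly-connected members,
and discards complexes smaller than 2. Scores are density × size;
confidence scores play no role after thresholding. The fluff stage is
deliberately not implemented (off in the workflow this mirrors).

## qPCR

Fold changes follow the Livak convention, 2^(−ΔCt) and 2^(−ΔΔCt), with a
`literal_sign` flag for the unsigned exponent reading (which inverts all
results). Technical replicates are averaged on the Ct scale; undetermined
(UD) targets propagate an undetermined result and are excluded listwise
with an exclusion count, never imputed; an undetermined reference is an
error. `ddct_from_replicates` treats technical replicates as the
dispersion unit when each group is one pooled sample, propagating the
replicate SD into the interval 2^(−ΔΔCt ± SD).

## Detectability and calibration utilities

The detectability estimate is pure arithmetic: cells = total/2 × cortical
fraction, moles = cells × copies / N_A, mass = moles × M × 10¹² pg/g,
rounded only at the reporting layer. The default Avogadro constant is the
printed 6.023×10²³ so the published figures reproduce digit for digit; the
CODATA value is provided alongside. Calibration ladders are top/2ⁱ,
fitted by unweighted OLS with inverse prediction; predictions outside the
ladder are flagged as extrapolated.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analysis assumes, at
desk scale: protein latent abundances ~ Normal(25, 2) on the log2 scale,
per-cell measurement noise SD 0.5, per-sample scale offsets ~ Normal(0,
0.3) for normalization to undo, a fraction `frac_de` of proteins with a
planted ±`effect_log2` shift (random sign, applied to all non-reference
groups; ground truth records the signed value), peptide counts
1 + Poisson(mean−1) so the 2-peptide filter has work to do, and ~1% decoy
plus ~1% contaminant rows. The default design is two groups of 4 — five
pooled samples with one removed, as in the cohort scheme this mirrors; the
six-group labelling (RM, RF, TMV, TFV, TMA, TFA) is expressible through
`SimConfig.groups`.

Missingness is logistic in log2 intensity: P(missing) =
logistic((midpoint − log2 I) × slope) with midpoint 22.0 and slope 2.0
(~9% missing cells overall). The sharp slope models an instrument
detection limit: a protein sits either above it (observed essentially
everywhere) or below (missing nearly everywhere and then failing the 80%
rule). This sharpness matters for null calibration — a shallow dropout
curve puts many proteins in a regime where one group can go fully missing
by chance, and single-value imputation then converts that asymmetry into a
confidently "significant" present/absent call. With the sharp default the
dual rule's empirical false-discovery proportion over 50 null replicates
stays within 0.05 + 3 Monte-Carlo SE; with soft dropout it would not,
which is a real property of noise-floor imputation, not of the test.

What the generator does **not** emulate: peptide-level quantification and
roll-up, match-between-runs correlation structure, intensity-dependent
variance trends, batch effects beyond a scalar per-sample offset, or
annotation structure beyond one planted enriched term. Passing tests
therefore certify the pipeline's statistical behavior under its own model
assumptions, not fidelity to any particular deposited dataset.

## Problem sizes and numerical choices

Simulation-based checks use 2000 proteins × 8 samples with 50 replicates
for null calibration and 3 replicates for recovery studies — sizes at which
Monte-Carlo error is small relative to the tolerances while a full suite
run stays interactive. Trigamma inversion tolerance is 1e−8; z
standardization is asserted at 1e−9; BH and hypergeometric results are
checked against exhaustive oracles at machine precision. Degenerate inputs
(all-identical ratios, zero variances everywhere, empty samples,
undetermined references) raise typed errors naming the offending entity
rather than returning NaNs.

## Known limitations

Single-value noise-floor imputation understates variance for heavily
imputed proteins; the per-group imputed-cell counts are reported alongside
every DEP table so such calls can be audited. The moderated model is
two-group only (no multi-factor designs, pairing, or variance-intensity
trends). Term levels are taken as input metadata; no ontology traversal is
performed. MCODE's fluff stage is not implemented. The kappa grouping uses
a single threshold for component formation (0.4) and exposes the 0.3
edge-drawing threshold separately, without attempting to resolve which of
the two governed the original figure layouts.
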