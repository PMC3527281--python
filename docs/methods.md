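# Methods

## Occupancy model

Each predicted binding site is modeled as an independent two-state system in
equilibrium with a reservoir of its miRNA.  With a tool-reported binding free
energy `E` (kcal/mol, typically ≤ 0) and chemical potential `μ = RT·ln[miR]`,
the occupancy is `p = 1/(1 + exp((E − μ)/RT))`.  The gene-level FD score sums
occupancies over all sites of all considered miRNAs; it is additive over
disjoint site lists, bounded by the site count, non-increasing in every site
energy and non-decreasing in every expression level.  Assumptions worth
stating explicitly:

- **No competition or titration.**  Sites fill independently; the miRNA pool
  is treated as an infinite reservoir.  Transfection-style saturation of the
  silencing machinery is outside the model.
- **Abundance units are arbitrary.**  Rescaling all levels by `c` shifts every
  μ by `RT·ln c`; an explicit `expression_scale` knob exposes this degree of
  freedom.  The occupancy model is informative only when μ lies within a few
  RT of the energy distribution (the responsive regime); with raw read counts
  and energies in physical kcal/mol a scale far below 1 is appropriate.
- **RT defaults to 0.6163 kcal/mol** (R = 1.987·10⁻³ kcal·mol⁻¹·K⁻¹ at
  310.15 K).  It sets the sharpness of the occupancy curve and is exposed in
  every scoring entry point.

For predictors without energies, the WSUM score weights each miRNA's summed
site scores by its relative expression within the analyzed miRNA set (the
denominator runs over the supplied set, not the whole miRNome).  Predictors
with binary site calls contribute site counts.  The naive baseline sums
oriented site scores with no expression input; energy scores are negated on
ingest there so "larger = stronger" holds for every combined table.

miRNAs absent from the expression table, or at level ≤ 0, have their sites
dropped with a logged warning in all combiners: only expressed miRNAs take
part in combinatorial scoring.

## Ensemble

Per-tool combined scores are assembled into a dense gene × tool matrix
(lexicographic order, missing gene-in-tool entries imputed 0, consistent with
"no detected sites" under additive combination).  A linear-kernel SVM
(C = 1 by default) is trained on features z-scored with training statistics;
the probability output is a sigmoid fitted to out-of-fold decision values
(5 seeded stratified folds), so the calibrated probability is monotone in the
SVM decision value.  Training is deterministic given the seed, and the model
serializes to a versioned JSON schema that round-trips to identical
predictions.

Cross-dataset application uses per-tool normalization maps stored in the
model: `rank` (default) replaces a new score with the training-reference
quantile at its empirical quantile — strictly order-preserving, average ranks
for ties, exact identity on the reference itself — and `mean` rescales to the
reference mean.  Rank normalization makes predictions invariant to any
monotone distortion of a tool's score scale, which is the property that
matters when a predictor's scores are not comparable across species or
releases.

## SNP ranking

For each SNP:miRNA pair the full pipeline is evaluated on the reference and
the variant 3'UTR.  Because the intended use is flagging variants that
destroy *confident* targets, the default ranking score is
`ΔP = P_ref·(P_ref − P_alt)`; the plain difference `P_ref − P_alt` is also
available and recorded in the output metadata.  The plain mode is
antisymmetric under ref/alt exchange; both modes are exactly zero when the
SNP leaves the site set and scores unchanged.  Pairs with ΔP above a
threshold (default 0.01) are reported, descending, with lexicographic
(snp_id, mirna_id) tie-breaks, and the end-to-end ranking is byte-identical
across reruns.  When no expression table is provided — the usual situation in
population-genetics screens — uniform abundance is assumed and logged.

The bundled seed scanner reports strict Watson-Crick matches (no G:U wobble)
of the canonical classes, 8mer > 7mer-m8 > 7mer-A1 > 6mer by priority for
multiply-classed windows, with surrogate energies (−1.0 / −0.75 / −0.75 /
−0.5 kcal/mol by class) on a deliberately compressed scale: they feed the
same FD machinery while making no pretense of thermodynamic accuracy.  Users
with real per-site energies supply them through the site-table interface
instead.

## Synthetic benchmark generator

The generator plants ground truth the pipeline can be scored against: sites
with true energies, read-count-like expression, and labels derived from true
FD occupancy (top half = positives by default, giving a balanced design; 284
genes yield 142/142).  Its default distributions encode the structure of the
real data the method is built for:

- **Expression:** log-normal (`meanlog = ln 5000`, `sdlog = 6`) floored at
  50 reads.  Cellular miRNA pools are extremely skewed — a handful of species
  dominates the read mass — and it is exactly this spread that makes
  expression-aware combination informative.  Read counts are converted to
  concentrations with a global scale placing the median chemical potential at
  the mean binding energy, i.e. in the responsive regime (see above; the
  scale is a unit choice, not a fit).
- **Sites:** Poisson(4) sites per gene; each site belongs to a per-gene
  primary miRNA with probability 0.7, else to a uniform miRNA.  Real UTRs
  under miRNA control often carry repeated sites of one regulator, and this
  clustering is what couples a gene's occupancy to the expression of
  particular miRNAs rather than to site count alone.
- **Energies:** normal(−8, 1) truncated at 0 kcal/mol.
- **Per-tool observations:** each of four tools (two energy-reporting, two
  score-reporting) re-scales site magnitudes with its own curvature exponent
  (1.0 / 1.6 / 0.7 / 1.3, anchored at the mean strength), adds 20%
  multiplicative and 0.5 kcal/mol additive noise, and drops sites with a
  strength-dependent probability (up to 60% for the weakest sites, near zero
  for the strongest).  This mirrors how real predictors behave: they agree on
  which sites are strong, disagree substantially on magnitudes and marginal
  calls, and correlate only partially with each other.

What the generator does **not** emulate: sequence composition, UTR length
structure, site accessibility/context effects, miRNA family redundancy, and
any form of inter-site cooperativity.  A passing benchmark therefore shows
that the pipeline recovers planted expression-dependent occupancy under
realistic inter-tool disagreement — not that it reaches any particular
accuracy on biological data.

## Evaluation toolbox

ROC curves threshold at every distinct score (trapezoidal AUC equals the
tie-aware rank statistic); AUC differences are tested with a hand-rolled
paired DeLong test (midrank structural components) or a paired stratified
bootstrap (≥ 2000 seeded resamples); degenerate zero-variance comparisons are
reported as such rather than NaN.  Precision-recall curves keep one point per
achieved recall (best precision, i.e. highest threshold).  For positive-only
datasets a sensitivity-vs-threshold curve is provided and explicitly flagged
as not a standard ROC.  Gene-set enrichment uses the upper-tail
hypergeometric.  The decile analysis sorts scored genes into score deciles
(decile 1 = highest) and compares each decile's per-gene response measure
with a disjoint reference gene set by the two-sample KS distance and the
two-sided rank-sum test (the groups are disjoint, so an unpaired rank test is
the appropriate form); deciles under 3 genes are flagged and skipped.

The additivity regression fits
`FC_lm ~ ℑ + a·FC_l + b·FC_m + c·FC_l·FC_m` and removes the least
significant slope while its p-value exceeds α = 0.05 (largest-p backward
elimination; the intercept is always retained).  Perfect fits leave
machine-noise coefficients whose t-statistics are meaningless, so a slope
numerically zero relative to the largest coefficient is treated as
insignificant.  Near-collinear designs (condition number > 1e10) trigger a
warning.

## Numerical choices and conventions

- Coordinates are 0-based half-open everywhere; SNP positions are offsets
  within the supplied 3'UTR, and the reference allele is checked against the
  sequence to catch convention bugs.
- The FD occupancy is evaluated through a numerically stable logistic, exact
  for `|E − μ|/RT` up to 1e4 and at the ±∞ limits.
- Top-fraction target calling uses the linear-interpolation quantile with
  boundary ties included, so tied score plateaus are never split.
- Input filters (3'UTR ≥ 50 nt keeping the longest isoform per gene; miRNA
  ≥ 50 reads, boundary inclusive) log their in/out counts.
- All emitted files are TSV/FASTA/JSON with '#'-metadata headers (version,
  config hash, seed) and are byte-identical across runs of the same
  configuration.

## Problem sizes

The bundled benchmark runs 2000 genes × 25 miRNAs per replicate with a 50/50
train/held-out split; the reported numbers average 50 replicates in
`scripts/acceptance.py` (100 in the test suite's directional check).  The
null calibration of the decile KS tests uses 1000 simulated datasets of 1000
scored genes against a 300-gene reference.  These sizes give stable estimates
(the held-out AUC standard error per replicate is about 0.01) while keeping
a full run in the tens of seconds on one CPU.

## Known limitations

Occupancy independence ignores site overlap and cooperativity; the SVM is
linear by design (no kernel search); the seed scanner handles neither
3'-compensatory pairing nor wobble pairing; the SNP workflow scores
single-nucleotide substitutions only (no indels, no genome-to-UTR liftover);
and MAF filtering is a pass-through column filter, never computed from
genotypes.
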