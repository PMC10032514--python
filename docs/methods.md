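# Methods

## Problem and data model

A scent signature is the relative abundance pattern of a few dozen skin
compounds (sebaceous-gland products, fatty-acid esters, steroid derivatives)
measured by GC×GC–TOFMS. The package answers an identification question:
given a query trace (scent residue recovered from a fired cartridge case)
and a panel of reference standards collected on glass beads, which reference
is most similar, and is that margin statistically meaningful?

Inputs are per-sample peak tables (peak id, both retention times in seconds,
area, optional compound label), a marker ladder, and a sample manifest
(subject, carrier, exclusion flag with mandatory reason). Exclusions are
data, not code: a contaminated sample is flagged in the manifest rather than
deleted.

## Retention-index alignment

Retention indices are piecewise-linear interpolations between ladder
markers, extended linearly beyond the outermost segment. Because the same
run-level distortion acts on markers and analytes, RIs are exactly invariant
under any affine drift of the time axis; this is tested as a property.
Siloxane contaminants serve as markers precisely because they appear in
every sample, blanks included, so the ladder is always resolvable; a sample
in which fewer than half of the markers can be located (by label, else by
nearest time within a window) raises an alignment error rather than
producing a silently misaligned column.

Cross-sample matching is greedy single-linkage on the sorted pooled RIs: a
new compound starts wherever the gap between consecutive RIs exceeds
`ri_tol` (default 5 RI units; the matching algorithm and tolerance are
repository conventions, chosen deterministic and order-independent).
Within a sample, co-eluting duplicates are summed, conserving total area.
The second retention dimension is carried as metadata only; matching uses
the first dimension, where the drift correction applies.

Blank subtraction drops every compound detected in any blank, except the
ladder markers, which must survive for alignment; marker columns are
identified by label prefix.

## Ratio features

`r_ij = a_i / a_j` for all ordered pairs i ≠ j. Zero divisors and
non-finite results map to zero, so zero uniformly encodes "undefined or
absent" (0/0 falls under the divisor rule). Self-ratios are excluded: they
are identically one with zero variance and would saturate any least-SD
ranking. Both orientations are kept; the reciprocal identity
`r_ij · r_ji = 1` (when both areas are positive) and invariance to global
rescaling of a sample's areas are tested properties. The transform is
deliberately not a log-ratio (CLR/ALR) — zeros are data here, not missing
values to impute.

## Model_N_T2 selection

Per subject: incidence filter at T1 (default 75%, i.e. nonzero in at least
75% of the subject's samples — eight of ten), then the N ratios with the
smallest intra-subject sample standard deviation (n−1 denominator; ties at
the cutoff broken by lexicographically smaller ratio id, making selection
deterministic). Zeros are included in the SD computation; all-zero columns
are already gone via the incidence filter. The per-subject sets are merged —
set union by default, since a second incidence threshold is only meaningful
on a set that still contains subject-specific ratios; an intersection mode
is exposed for the stricter reading — and filtered at T2 computed over all
pooled samples (standards plus queries when both exist). An empty result
raises an error advising a lower T2.

Grid optimisation ranks every (N, T2) pair — defaults N ∈ {25…500 step 25},
T2 ∈ {25, 50, 75}% — by the cumulative explained variance of the first
min(7, rank) principal components of the selected-ratio matrix, ties broken
toward smaller N then smaller T2. PCA here is a ranking heuristic, not an
inference step.

## Multivariate statistics

Mardia's statistics use the maximum-likelihood (1/n) covariance:
b1,p is the mean cubed Mahalanobis cross-product, b2,p the mean squared
Mahalanobis distance; n·b1p/6 is referred to χ² with p(p+1)(p+2)/6 df and
(b2p − p(p+2))/√(8p(p+2)/n) to the standard normal. With far more ratios
than samples the covariance is singular, so the test refuses and instructs
reduction to PCA scores first; the pipeline applies it to the first three
components. The implementation is checked against a hand-evaluated
point-symmetric fixture (b1p = 0, b2p = 4), affine invariance, and a
Monte-Carlo calibration under normality.

PCA is mean-centred SVD without unit-variance scaling — ratio features are
already dimensionless and share a scale; standardising would up-weight the
noisiest ratios.

## Classification benchmark

Grids: KNN k ∈ 1…19 × {uniform, distance}; radius-NN radius ∈ 1…91 step 10
with the same weights; random forest estimators ∈ 1…191 step 10,
max_features ∈ {1,3,5,7,9,11} (clipped to the feature count), bootstrap
on/off, OOB scoring explored only when bootstrap is on. Model selection is
grid search with stratified 5-fold cross-validation scored by accuracy on a
stratified 75/25 split; the held-out quarter is scored with macro-F1
(strictest under class imbalance). Radius-NN queries with no neighbour in
the radius get a reserved outlier label that counts as an error. When the
smallest training class has fewer members than the fold count the fold
count degrades to that size with a warning — tiny real-world class sizes
make strict 5-fold infeasible. The PC-space variant fits the PCA on the
training split only and projects the test split, avoiding leakage. All
randomness is seeded; identical seed and inputs reproduce the report
exactly.

## Similarity identification

Cosine, Pearson, Spearman (average ranks) and Kendall tau-b (tie-corrected)
— tie handling matters because zero ratios create large tied groups. A
constant vector makes the correlation methods undefined and raises, never
silently scoring zero. A comparison row scores one query against every
panel member; the prediction is the subject of the best-scoring reference.
Exact score ties are reported and never broken silently: a tied row counts
as incorrect unless the tied subjects coincide. Open-set queries (true
subject absent from the panel) are scored and counted incorrect. Both query
directions (cartridge→standards and standards→cartridges) are supported.

The top-two test Fisher-transforms the two best correlations and uses the
independent-correlations form `z = (z₁ − z₂)/√(2/(n−3))` with two-sided
normal p, where n is the length of the model-restricted ratio vector the
correlations were computed over. The two scores share the query vector, so
they are not strictly independent; Steiger's dependent-correlations variant
(requiring the correlation between the two reference vectors) is exposed as
an option. The embedded reference table of published top-two score pairs is
used only to check that the test reproduces the reported significance
verdicts — the published p-values themselves encode an unstated effective
n and are not reproduced.

## Synthetic cohort generator

What it emulates: subject-specific compound profiles (per-compound log10
mean areas drawn once per subject), log-normal within-subject variability,
per-peak dropout, shared contaminants including the marker siloxanes
(present in blanks, never dropped out for markers), a firing transform
(attenuation of the top-RI third of scent peaks, extra dropout, added
lubricant-cloud alkanes in the early-eluting region), and per-sample affine
retention drift plus per-peak jitter.

Defaults, chosen once as a realistic desk-scale regime:

| parameter | default | rationale |
|---|---|---|
| `n_compounds` | 75 | cohort panel size |
| `n_shared_contaminants` | 10 (6 markers) | siloxanes + lab background |
| `subject_profile_sd` | 0.8 log10 units | inter-individual VOC abundance spread of one to two orders of magnitude |
| `intra_cv` | 0.4 (ln-scale σ) | ≈40% repeat-measurement CV, typical for untargeted GC peak areas |
| `dropout_p` | 0.05 | occasional sub-LOD peaks |
| `firing_attenuation` | 0.3 on top-RI third | fired samples lose intensity in the least-volatile region |
| `firing_dropout_p` | 0.1 | additional peak loss on firing |
| `cloud_compounds` | 15 | lubricant alkane cloud |
| drift | slope ±3%, offset ±5 s, jitter σ 0.5 s | run-to-run retention variation correctable by the ladder |

Compound positions sit on an even rt1 grid kept ≥12 s clear of the marker
positions, so true RI separations (≈10 RI units) comfortably exceed the
clustering tolerance; overlap-induced compound loss is then a property of
noise, not of the layout. All randomness derives from one seed through
named `SeedSequence` children, so cohorts are bit-reproducible.

What it does **not** emulate: mass spectra, chromatographic peak shapes,
modulation-period quantisation of the first dimension, correlated compound
chemistry (e.g. ester families rising together), matrix effects, or
real-world environmental contamination. Passing tests therefore demonstrate
that the algorithms recover planted structure under the stated statistical
assumptions — not field performance on real chromatograms.

## Numerical choices and degenerate inputs

* Ratio division is computed as true element-wise division so results agree
  bit-for-bit with the scalar definition.
* Least-SD ties break lexicographically; comparison-row score ties are
  reported, not broken.
* `|r| = 1` makes the Fisher transform infinite and raises; n ≤ 3 likewise.
* Near-singular covariance (condition number > 1e12) is treated as singular.
* Matrix CSVs round-trip floats through Python's shortest-repr formatting,
  so written values re-read bit-exactly.

## Problem sizes used in tests and the acceptance script

Desk-scale cohorts: 10 subjects × (1 standard + 1 cartridge) for
identification recovery (5 seeds), 5 subjects × 10 standards for model
development, 3×12 separable clusters for the classifier checks. These sizes
were chosen to exercise every code path with comfortably fast runs while
matching the study-scale structure (panel of ~75 compounds, single-digit
subject counts per experiment).

## Known limitations

* The RI-clustering tolerance is global; heavily co-eluting compounds merge
  (and are then lost to blank subtraction if the partner is a contaminant),
  mirroring how co-elution with background is handled in practice.
* The top-two test's n is a modelling choice (the model vector length); the
  scores' dependence through the shared query vector is only addressed by
  the optional Steiger variant.
* The classifier benchmark degrades the fold count for very small classes
  rather than refusing; reports state the folds used via a warning.
* Identification is closed-set: no score threshold is calibrated for
  "none of the panel" answers.
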