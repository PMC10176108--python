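# Methods

`ptyrlink` implements a desk-scale, fully testable version of a common
systems-biology analysis chain: multiplexed phosphotyrosine (pTyr)
time-course proteomics is reduced to per-peptide response features, explored
with unsupervised methods, and linked to quantitative cell phenotypes with
cross-validated latent-variable regression. This note records the models,
the defaults and their rationale, the synthetic study the package uses in
place of deposited data, and the numerical conventions.

## Experimental design being modeled

Nine cell lines expressing EGFR variants (wild type, six single Y→F
point mutants of C-terminal tyrosines, and two multi-site mutants, DY5 and
DY6) are stimulated with EGF and sampled at 0, 30, 60, 120 and 300 s in
three biological replicates. Samples are multiplexed by timepoint into TMT
10-plexes: each plex carries the nine lines at one timepoint plus one
bridge ("batch") channel — the WT 2-min sample — shared by every plex so
runs can be placed on a common scale. Channel assignment is scrambled
between replicates to avoid channel bias. Phenotypes measured per line:
proliferation (confluency imaging ± EGF), migration (scratch-wound closure
± EGF), and receptor internalization (pH-sensitive EGF conjugate
fluorescence against an untransfected control).

## Preprocessing model

1. **PSM quality filter.** A peptide-spectrum match is kept iff
   rank = 1, ion score > 15, isolation interference < 40%, and mean
   reporter signal > 1,000, with all bounds strict; records with any
   missing reporter channel are dropped (configurable). "Mean signal" is
   the arithmetic mean over non-missing channels, computed independently of
   the missing-channel rule.
2. **Rollup.** Reporter intensities are summed over PSMs per unique
   phosphopeptide, where peptide identity is sequence + ordered
   modification-site string (so singly and doubly phosphorylated forms are
   distinct). A protein-level rollup (same contract, keyed by protein) is
   provided as a convenience.
3. **Loading normalization.** Each channel is divided by its crude-lysate
   median relative to the geometric mean of the run's medians. Only
   channel *ratios* are identified by loading data; the geometric-mean
   centering is a convention that cancels in the fold-change step.
4. **Bridge normalization.** Within each run, each peptide's channels are
   divided by that peptide's bridge-channel value (internal-reference
   scaling). A per-run global-factor variant (divide the run by the median
   bridge intensity) is available behind `method="global_factor"`. A
   peptide without a bridge value in a run is missing for that run's
   samples. Missingness propagates everywhere; nothing is imputed.
5. **Basal normalization.** Each (line, replicate) trajectory is expressed
   as log2 fold change over its own 0 s sample; 0 s columns become exactly
   zero and are retained. This cancels per-line basal-state differences
   and any residual per-run scale.
6. **Presence filter.** Peptides are kept when every (line, timepoint)
   condition has at least `min_replicates_per_condition` quantified
   replicates (default 2 of 3).

Two invariances follow from this construction and are enforced by tests:
scaling any run by a positive constant leaves basal log2FC unchanged, and
with exact loading factors the chain is an exact inverse of the generative
model (noise-free recovery to 1e-9).

## Time-course features and responsiveness

The headline per-(peptide, line) feature is the **AUC**: the trapezoidal
integral of log2FC over the measured timepoints (log2FC·seconds), with no
interpolation or resampling; negative excursions contribute negatively.
AUC is computed on replicate-mean trajectories for modeling; per-replicate
AUC is available for variance estimates. Per-timepoint log2FC features
(stimulated timepoints only) and a combined mode are alternatives.

Responsiveness calls use a two-sided one-sample Student's t test of
replicate log2FC against 0 per (peptide, stimulated timepoint) — basal
normalization reduces the stimulated-vs-unstimulated contrast to a
one-sample test. A peptide is responsive when any stimulated timepoint has
P < α (default 0.05), uncorrected, matching the plain P < 0.05 convention
for this analysis; Benjamini–Hochberg correction is available but off by
default. Cells with fewer than two replicates or zero variance are
untestable and excluded from the denominator.

## Multivariate exploration

PCA is computed by SVD of the column-centered matrix (unit-variance
scaling off by default: log2FC features are already on a common scale;
both flags are exposed). Hierarchical clustering uses Pearson correlation
distance d = 1 − r with average linkage by default; the cell-line
dendrogram clusters the line × peptide-AUC matrix. Correlation maps reuse
the same machinery and export a clustered leaf ordering; dendrograms are
exported as Newick.

## Consensus SOM co-clustering

A batch self-organizing map on a 5×5 hexagonal lattice (Euclidean metric)
is trained on peptide trajectory vectors; for differential analysis the
input is the concatenation of two lines' stimulated-timepoint trajectories
(identically-zero 0 s columns are excluded to avoid degenerate
dimensions). Batch training — each epoch assigns every peptide to its
nearest unit and moves unit weights to Gaussian-neighborhood-weighted data
means — is deterministic given the initialization, so the restart ensemble
is the sole randomness source: unit weights are initialized uniformly in
the bounding box of the data's top-two principal-component plane, the map
is retrained `n_restarts` times (default 1,000; the pipeline's desk-scale
default is 200), and the co-clustering frequency of every peptide pair
(fraction of restarts sharing a best-matching unit) is recorded.
Consensus clusters come from average-linkage hierarchical clustering of
the frequency-matrix rows under Euclidean distance.

Schedule defaults: 100 epochs; neighborhood radius decays linearly from
max(grid)/2 to 2.0. The final radius is deliberately kept at about the
inter-unit spacing: if the neighborhood shrinks further, the converged map
places several nearly identical units inside each coherent trajectory
cluster, members split across those units restart by restart, and
within-cluster co-frequency collapses toward 1/k even for perfectly
separated clusters. With the default schedule, planted partitions whose
centroid separation is ≥ 5× the within-cluster noise SD are recovered
exactly (adjusted Rand = 1) and within-cluster co-frequencies exceed 0.9.

Cluster trajectory bands report, per timepoint, the mean across the
cluster's peptide trajectories and a t-based 95% CI with df = n_peptides −
1; singleton clusters yield a mean with an undefined (flagged) CI.

## Phenotype reduction

* Proliferation: slope of ln(confluency) vs time over a configurable
  window (exponential growth rate, 1/h). An exponential rather than
  logistic fit is used because the assays are read in the sub-saturation
  regime where the two coincide; the PLSR target is the EGF-minus-control
  delta rate.
* Migration: negative least-squares slope of wound width vs time on the
  pre-closure window (points strictly before the first fully closed
  frame), in width units/h; target is again the EGF delta. Wound
  confluency can be supplied as the width column for the secondary metric.
* Internalization: mean sample fluorescence over the untransfected control
  mean (dimensionless, scale-invariant), per replicate when a matched
  control replicate exists.

## PLSR with LOOCV and VIP

Single-response NIPALS PLSR per phenotype (three separate models) on
mean-centered, autoscaled X (scaling on by default so VIP is comparable
across heterogeneous feature magnitudes; toggle exposed). Components are
extracted with X-deflation; coefficients are b = W(PᵀW)⁻¹q. A constant
response is a documented degenerate case: zero components, zero
coefficients, R² = 0 by convention.

Leave-one-out cross-validation refits centering/scaling inside every
fold; Q²(A) = 1 − PRESS(A)/TSS with TSS about the full-data mean (a
training-fold-mean variant is not used; the convention is logged here).
The selected component count is the smallest A maximizing Q², with a
default cap of 3 components — the headline models are three-component
fits. VIP scores use SS_a = q_a²·t_aᵀt_a and satisfy ΣVIP² = p exactly;
the selection threshold defaults to 1.5. Cumulative VIP sums scores across
the three phenotype models, ranked descending with lexicographic
tie-breaks. Robustness refits drop designated lines (default Y845F and
Y1045F, the expression outliers in this design) and report R², Q² and the
Spearman correlation of VIP ranks against the full model.

A small-sample caveat, measured with this package's own null experiments:
at n = 9 observations and p = 200 features, a pure-noise phenotype yields
a *positive* LOOCV Q² in roughly 7–9% of random draws, whether or not the
component count is selected by CV (CV selection adds a further optimistic
bias under the null). Q² thresholds well above zero — such as the 0.5 used
in the recovery suite — are therefore the meaningful notion of
predictivity at this design size, and the null-calibration check evaluates
the predetermined three-component model rather than a CV-selected one.

## Synthetic study generator

The generator emulates the full design so every stage is testable without
deposited data. What it does and does not reproduce:

* **Trajectories.** Responsive peptides (default 60%) follow
  log2FC(t) = a·(1 − e^(−t/τ))·e^(−t/κ) with per-axis (τ, κ) drawn from
  [20, 120] s and [150, 2500] s — the two-parameter family covers both
  transient and sustained responses — scaled by a per-(peptide, line)
  amplitude and a per-(axis, line) modulation. Non-responsive peptides are
  flat. True log2FC at 0 s is exactly zero.
* **Intensities.** Base abundances are log-uniform over [10^3.5, 10^7]
  (spanning the >1,000 signal filter); per-channel intensity is base ×
  2^(log2FC + basal offset) × loading factor × lognormal noise. A clean
  PSM whose mean reporter falls at or below the signal gate is uniformly
  rescaled upward (ratio-preserving) so that clean records pass QC by
  construction. Crude-lysate medians are exactly proportional to the true
  loading factors; crude-median estimation error is not modeled.
* **Design.** One plex per (timepoint, replicate): 9 line channels + 1
  bridge (WT 120 s), with the channel assignment permuted per run to
  emulate labeling-scheme scrambling.
* **Junk PSMs.** A configurable fraction of records each violate at least
  one quality rule (rank, score, interference, low signal, missing
  channel), with the violation recorded so the filter's audit can be
  checked exactly. Per-channel missing-at-random dropout (default 1%)
  gives the presence filter realistic run-level attrition; with the
  default design this yields a funnel of roughly 300 quantified → ~260 at
  ≥2 replicates → ~110 at all replicates.
* **Phenotypes.** Five planted peptides per phenotype define a
  standardized score per line from their true AUC z-scores; raw assay
  tables (exponential confluency curves, linear wound decay, control-
  normalized fluorescence) are rendered so the phenotype module's fitted
  delta rates track the planted scores linearly (log-linearly for
  internalization).

Not emulated: raw spectra, chromatographic or charge-state effects,
peptide-level variance heterogeneity calibrated to any real dataset,
informative (non-random) missingness, and saturating phenotype kinetics.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated statistical structure — not performance on
any particular real dataset.

Two auxiliary fixtures support the regression validation suite.
`make_planted_regression` builds a 9 × 200 feature matrix with the
correlation structure of co-regulated AUC features: all features load on
two shared latent response axes (loading 0.8) plus unit idiosyncratic
noise, and the five planted features track the first axis tightly
(idiosyncratic SD 0.1, standardized effect ≈ 1 each); the response is
their sum plus noise at 0.2× the signal SD. `make_null_regression` has no
association structure anywhere (idiosyncratic features and response) and
is the null for the Q² calibration check.

## Problem sizes and numerical conventions

The default pipeline runs the full chain at 300 peptides, 15 plexes,
200 SOM restarts × 50 epochs; the validation suite uses 20 seeds for
planted-recovery rates, 50 for null calibration, 100 for phenotype-rate
recovery, 2,000 tests for type-I calibration, and 150 peptides × 200
restarts for SOM consensus. Phenotype fixtures are sampled at live-imaging
density (hourly confluency over 48 h, half-hourly wound width): at
sparser grids the ±5% noisy-recovery bound is unattainable for purely
statistical reasons (the slope standard error alone exceeds it).

Determinism: a single pipeline seed fans out via SHA-256 to per-stage
seeds; SOM restarts use seeds spawned from a `SeedSequence`; batch SOM
training is deterministic given its initialization. All matrices persist
with shortest-exact float representation, so a rerun under the same seed
is bit-identical and read → write → read is the identity. Ties in
hierarchical clustering follow SciPy's conventions; VIP rank ties are
broken by feature id; Q² component-count ties resolve to fewer components
(tolerance 1e-12). Degenerate inputs (constant response, zero-variance
vectors, singleton clusters, empty peptide sets) raise typed errors or
return flagged values as documented in the respective docstrings.

## Known limitations

* Observations for regression are the nine cell lines; no model here can
  escape n = 9, and Q² estimates at this size are noisy (see the PLSR
  caveat above).
* The SOM consensus is validated against planted partitions, not against
  any particular published map; with real, continuous (non-blob) data the
  co-clustering matrix is informative but clusters are not atomic.
* The bridge design assumes the bridge sample is quantified in every run
  for every peptide of interest; peptides missing from a run's bridge are
  lost for that run rather than rescued.
* Counts such as "59% responsive" or the 869/254/217-style funnel are
  properties of a dataset, not of the method; the synthetic defaults
  reproduce their shape, not their exact values.
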