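# Methods

This note documents the models, parameter choices and numerical
conventions behind `cytoglia`, and what the synthetic-data tests do and
do not establish about real data.

## Study design emulated by the simulator

The pipeline targets CyTOF time-course experiments on primary glial
cultures: microglia alone or mixed with astrocytes, stimulated with LPS
or Poly(I:C), sampled at t = 0, 5 min, 15 min, 30 min, 1, 2, 4, 8, 24
and 48 h, three independent replicates per condition.  Samples are
barcoded with unique 3-of-6 combinations of six palladium isotopes,
pooled, spiked 1:20 with EQ four-element calibration beads
(Ce/Eu/Ho/Lu), and acquired in one batch.  A full time course at three
replicates (30 samples) exceeds the 20 codes of a 6-choose-3 key, so a
"run" is one pooled barcode set of up to 20 samples; the study drivers
process one pool per replicate and concatenate the gated events.

The default panel carries the 13 identity markers used for
identity-round clustering (Olig2, CD11b, fibronectin, GFAP, CD68, F4/80,
CD45, Ly6C, Sox2, CD40, Galectin-1, Cx3CR1, CD86), 15 named
phospho-/state markers (pp38, pERK, pRSK, pCREB, pS6, pSTAT1, pSTAT3,
pNFκB, pSrc, pAkt, pcJun, pγH2AX, β-catenin, Ki67, cleaved caspase-3),
the six palladium barcode channels, five bead channels, an Ir191 DNA
intercalator, and the instrument's event-length and center parameters.
The full conjugation plan of a real 33-marker panel is not modeled; the
named markers are the ones the analyses depend on.

## Marker response model

Each responsive marker follows a pulse with five interpretable
parameters: baseline intensity `B` (ion counts), peak fold `F`, onset
and peak times, a decay time constant `τ`, and a persistent fraction
`p ∈ [0, 1]`:

- flat at `B` before onset;
- geometric (log-linear) interpolation from `B` to `B·F` between onset
  and peak;
- exponential relaxation toward the plateau `B·(1 + p·(F − 1))` after
  the peak.

Declining markers (the homeostatic receptor Cx3CR1) use `F < 1` with
`p = 1` (persistent downregulation).  The functional form is a modeling
choice — only the peak amplitudes and timings are externally
constrained — so all recovery checks target amplitude and timing, never
the curve shape.  Anchored amplitudes: pERK 16.8-fold at 15 min (LPS)
vs. 3.8-fold at 30 min (Poly(I:C)); pS6 25-fold at 1 h (LPS); CD40
9-fold (LPS) / 20-fold (Poly(I:C)) peaking at 24 h; in mixed cultures
CD40 is capped at 1.8-fold and the pS6/pCREB/pSTAT1/pSTAT3 responses are
halved.  Non-anchored baselines and amplitudes are order-of-magnitude
choices for primary microglia and are deliberately not treated as
recovery targets.

Per-cell intensities are lognormal around the dynamics-implied mean with
a mean-preserving parameterization (`σ² = ln(1 + cv²)`, default
cv = 0.3): CyTOF ion counts are strictly positive and right-skewed.
Artifacts: doublets are channel-wise sums of two events drawn from the
pooled stream (so a fraction merge two differently barcoded samples)
with doubled event length and averaged center; dead cells retain their
marker profile but lose ~92% of intercalator signal and gain cleaved
caspase-3; beads are high in all five bead channels and low elsewhere;
sensitivity drift is a smooth exponential decay over acquisition order,
defaulting to a 2× end-of-run loss.  Bead counts are binomial over the
cell count at rate 1/21 (the 1:20 spike).  All generators take explicit
seeds and are bitwise reproducible.

## Two kinds of planted truth

Bulk fold-change recovery and per-cell state recovery pull the simulator
in different directions, so two generators carry the ground truth:

- `simulate_run` plants *population-level* dynamics — every microglial
  cell at time t shares the dynamics-implied mean — so replicate-mean
  fold changes recover the planted peak folds exactly up to sampling
  error.  It also plants the sample/bead/doublet/dead/population truth
  used by the normalization, debarcoding and gating checks.
- `simulate_signaling_states` plants a *per-cell mixture* of four
  signaling archetypes (baseline-low; MAPK: pERK/pp38/pRSK/pCREB-high;
  pSTAT1-high; CD40/CD86 reactive) whose weights shift over the time
  course.  Prevalence anchors: the MAPK archetype peaks at 73% of cells
  (LPS, 15 min); the reactive archetype holds 56.4% / 53.4% / 39.8% /
  3.68% of cells at 48 h in LPS-microglia / LPS-mixed / PIC-microglia /
  PIC-mixed.  Weights between design time points are linearly
  interpolated.

With four clusters, the baseline-return RMSE contrast between
PIC-microglia and PIC-mixed is larger than it would be in a ~20-cluster
analysis of real data, where many unchanged clusters dilute the metric;
the direction (mixed returns far closer to baseline) is the meaningful
property.

## Normalization

Bead classification requires an event to exceed a per-channel threshold
in *all* bead channels; thresholds come from a 2-means split of the
arcsinh-transformed channel (or an explicit quantile).  Fewer than 50
bead events abort normalization.  Drift is fitted as per-window
(default 500 beads) per-channel medians over acquisition order; the
scalar correction at a window is the geometric mean over bead channels
of `global_median / window_median` — drift is treated as
mass-channel-wide, matching how a single detector sensitivity loss acts.
Factors are linearly interpolated between window centers, extended to
the run boundaries by log-linear extrapolation, and clamped to
[0.1, 10].  All non-instrument channels are corrected; event length and
center are physical shape summaries and are left untouched.  Beads are
removed after correction; the Ce140 gate downstream catches stragglers.
Quality criteria: corrected windowed bead medians flat within 2%, and a
refit on corrected data within 2% of unity.

## Debarcoding

Barcode channels are rescaled channel-wise by the 95th percentile of
their positive values, then each event is divided by its own maximum, so
the top channel reads 1 and separations are comparable across staining
intensities (the rescaling is invariant to per-channel gain).  The top
three channels form the candidate code; events whose candidate is not in
the key, or with all-zero barcode signal, stay unassigned (ties between
the 3rd and 4th value give separation 0).  Mahalanobis distances use the
six *raw* (normalized) barcode channels per assigned sample, with
covariance regularization ε = 10⁻⁶ · trace/6 on the diagonal; samples
with fewer than 7 events get distance 0 with a warning.  Default filter
thresholds — separation ≥ 0.3, Mahalanobis ≤ 30 — are package decisions
(interactively set in the original workflow) and are config-exposed; the
bc_neg cut is off by default because barcode negativity is normally
consumed during clean-up gating, but a per-sample 95th-percentile cut is
available and removes ≥ 80% of assigned cross-sample doublets in the
tests.

## Gating

Interactive polygon gates are replaced by one-dimensional thresholds and
rectangular two-channel regions so the cascade is reproducible and every
bound is overridable.  Thresholds are estimated on arcsinh(x/5)
intensities, on the events surviving the preceding gates: 2-means
bimodal splits for viability/cerium/CD11b/CD45/GFAP, central quantile
intervals (1–99%) for event length and center, and a 99.5% upper length
bound inside the viability gate.  A split is only accepted when the two
modes are separated by at least 2.5× their larger within-mode SD and by
an absolute 0.5 arcsinh units; otherwise the gate falls back to a
permissive quantile (2% for positivity gates, 99% for negativity gates)
with a warning — a positivity gate on a channel that is uniformly
positive should keep nearly everything.  "GFAP-negative" means below the
fitted GFAP split; "double-positive" means above both the CD11b and CD45
splits.  Attrition is recorded per gate and is monotone by construction;
a gate that removes every surviving event halts the cascade with a
diagnostic naming it.

## Fold-change statistics

Per-sample marker means are arithmetic means of raw (bead-normalized,
untransformed) intensities — the reported magnitudes are ion-count
ratios, so no arcsinh transform is applied here.  The vehicle is the
t = 0 sample of the same condition and replicate; log2 ratios are
averaged across replicates (average of log2 ratios, per the
heatmap-layer convention), which makes the replicate-mean linear fold a
geometric mean.  Markers with a zero vehicle mean are excluded with a
diagnostic; samples under 50 events are flagged low-confidence; empty
strata are missing, never zero.  Maximal condition divergence is the
signed value of `a − b` at the time point maximizing `|a − b|`.
Significance testing (two-way ANOVA with multiple-comparison correction)
is deliberately out of scope: the module exports tidy tables that any
stats package consumes directly.

## Clustering

Features are arcsinh(x/5) scaled per marker by the 99.5th percentile of
transformed values.  Partitioning is Leiden community detection
(modularity / RB-configuration objective, 2 iterations, explicit seed)
on an undirected k-nearest-neighbor graph (Euclidean, k = 15 — the same
neighborhood size as the UMAP embedding, since no separate value is
externally fixed).  Labels are 1-based, ordered by descending size.

Round 1 clusters on the 13 identity markers and excludes clusters whose
median CD11b or CD45 falls below the global 25% quantile, or whose
median GFAP exceeds the global 75% quantile — with each threshold
guarded by a 0.5-arcsinh-unit margin from the global median so that
homogeneous pure cultures (where those quantiles sit inside the single
mode's noise) keep all clusters.  Round 2 clusters the retained events
on all markers except CD11b, CD45, GFAP and Olig2, with the resolution
searched over a geometric grid until the cluster count lands in a
configurable band (default 15–25 for real-scale data; the archetype
tests use 3–6); an unreachable band returns the nearest count with a
warning.

Cluster annotation z-scores each marker's vector of cluster means
(arcsinh scale) across clusters using the population SD (ddof = 0);
"hi" at z ≥ 1.5, "lo" at z ≤ −1.5; zero-variance markers get z = 0.
The population convention matters at small cluster counts: a marker
elevated in exactly one of K clusters tops out at z = √(K−1), so the hi
rule can fire from K = 4 up — with the sample SD it would cap at
exactly 1.5 and never fire there.

Abundance trajectories are per-replicate cluster fractions averaged per
(condition, time), renormalized to sum to 1 per time point; the
time-normalized layer divides each cluster's series by its own sum
across time, and clusters are ordered by ascending abundance-weighted
mean time index, so early-emerging clusters rank first.  The
baseline-return RMSE is `sqrt(mean_c (f_c(t_end) − f_c(t_0))²)` with 0
as the expected value, on the fraction scale by default.  UMAP uses
15 neighbors, Euclidean metric, local connectivity 1, 2 components,
1000 epochs and a fixed seed, and feeds visualization only.

## Problem sizes

The test-suite and the acceptance script run entirely on synthetic data
at desk scale, chosen as the smallest sizes at which the statistical
checks are well-powered: 50,000-cell pooled runs for
debarcoding/normalization, ~30,000-cell artifact-spiked runs for gating,
5,000 events/sample × 10 time points × 3 replicates per arm for
fold-change recovery, and 150–200 cells/sample for the clustering
archetype analyses.

## What passing tests do and do not show

The simulator plants clean lognormal populations, well-separated barcode
codes, a single smooth drift and idealized artifacts.  Passing tests
demonstrate that the pipeline's logic is correct and self-consistent —
it recovers what was planted, at the planted times, under the planted
artifact load.  They do not demonstrate robustness to features of real
runs the generator does not model: isotopic spillover between adjacent
masses, ion-cloud fusion physics beyond the length/center summary,
heavy-tailed staining artifacts, plate effects between barcode sets, or
drifting bead-cell coincidences.  On real deposited data, gate placement
varies with the analyst; the defaults here are reproducible starting
points, not re-creations of any particular manual analysis.

## Known limitations

- FCS support is a minimal float32 FCS 3.1 single-dataset reader/writer
  (list-mode, `$DATATYPE F`); integer/double data types, multi-dataset
  files and vendor extensions are out of scope.
- Compensation/spillover correction is not implemented (not standard for
  this panel design).
- Doublet rescue/splitting and probabilistic barcode assignment are
  non-goals; ambiguous events are discarded, not recovered.
- The archetype mixture treats signaling states as discrete; real
  microglia move through continuous intermediate states, which blurs
  cluster boundaries in ways the ARI checks do not probe.
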