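# cytoglia

Time-resolved single-cell mass cytometry (CyTOF) analysis of glial
signaling, as a tested, reusable Python pipeline.

## The problem

Microglia — the resident immune cells of the CNS — mount fast,
stimulus-specific signaling responses to inflammatory challenges such as
the bacterial endotoxin LPS (a TLR4 agonist) and the viral mimetic
Poly(I:C) (a TLR3 agonist).  Measuring those responses at single-cell
resolution over a 48-hour time course requires a chain of preprocessing
and analysis steps that are usually performed interactively and are hard
to reproduce: calibration-bead drift normalization, combinatorial
palladium debarcoding, clean-up gating, vehicle-normalized fold-change
statistics, and graph-based clustering of signaling states.

`cytoglia` implements that chain end to end for experiments of this
design — 33-marker panels (identity + phospho-signaling markers), 3-of-6
palladium barcoding, EQ four-element calibration beads spiked 1:20, ten
time points (0, 5 min, 15 min, 30 min, 1, 2, 4, 8, 24, 48 h), two
stimuli (LPS, Poly(I:C)), microglia-only and microglia + astrocyte
cultures, three replicates — together with a synthetic-run generator
that plants known ground truth for every stage, so each step of the
pipeline is testable against an oracle.

## What it computes

- **Bead normalization** — events high in *all* bead channels
  (Ce140/Eu151/Eu153/Ho165/Lu175) are classified as calibration beads;
  windowed bead-channel medians over acquisition order give a
  multiplicative correction `f(i) = median_global / median_local(i)`
  (geometric mean over bead channels, linearly interpolated, clamped to
  [0.1, 10]) applied to every mass channel.
- **Debarcoding** — per event, the three highest rescaled palladium
  channels form the candidate code; quality statistics are the
  *barcode separation distance* (3rd − 4th ranked rescaled value), the
  within-sample Mahalanobis distance over the six raw barcode channels,
  and *bc_neg*, the summed raw intensity of the three channels expected
  to be zero under the assigned code (high bc_neg flags multi-cell
  events).
- **Clean-up gating** — a declarative, auditable cascade: debarcode
  quality → singlets (event length × center) → viability (DNA
  intercalator) → residual-bead removal (Ce140) → CD11b⁺CD45⁺ →
  GFAP⁻, with data-driven thresholds on arcsinh(x/5) intensities.
- **Fold-change time courses** — per-marker mean intensities per sample;
  log2 fold changes over the matched t = 0 vehicle of the same
  replicate, averaged across replicates; signed maximal divergence
  between conditions.
- **Two-round Leiden clustering** — round 1 on 13 identity markers with
  exclusion of low-CD11b / low-CD45 / high-GFAP clusters; round 2 on all
  markers except CD11b, CD45, GFAP, Olig2; cluster × marker z-scores
  with "hi" (z ≥ 1.5) and "lo" (z ≤ −1.5) annotations; per-condition
  cluster-abundance trajectories, time-normalized ordering, the
  baseline-return RMSE
  `sqrt(mean_c (fraction_c(48 h) − fraction_c(0 h))²)`, and a UMAP
  embedding (15 neighbors, Euclidean, 2 components, 1000 epochs) for
  visualization.

## Worked example

`examples/03_fold_change_timecourse.py` simulates three replicate pooled
runs per condition, normalizes, debarcodes, gates microglia and reports
peak vehicle-normalized fold changes:

```
LPS / microglia_only  (gated microglia: 38029)
  pERK     peak  16.60-fold at t = 0.25 h
  pS6      peak  25.07-fold at t = 1 h
  pSTAT1   peak  12.07-fold at t = 2 h
  CD40     peak   9.10-fold at t = 24 h
  Cx3CR1   peak   0.35-fold at t = 48 h

PIC / microglia_only  (gated microglia: 38029)
  pERK     peak   3.80-fold at t = 0.5 h
  ...
LPS / mixed  (gated microglia: 27672)
  CD40     peak   1.83-fold at t = 24 h
```

The recovered peaks match the planted study conditions: a strong early
MAPK burst under LPS (16.8-fold pERK at 15 min) that is blunted and
delayed under Poly(I:C) (3.8-fold at 30 min), a 25-fold pS6 peak at 1 h,
late CD40 upregulation (9-fold LPS / 20-fold Poly(I:C)) that astrocyte
co-culture caps below 2-fold, and progressive downregulation of the
homeostatic marker Cx3CR1 (fold < 1).

`examples/04_two_round_clustering.py` runs the clustering workflow on
the archetype simulation and prints the hi/lo annotation table, the
early-to-late cluster ordering (MAPK → pSTAT1 → CD40/CD86) and the
baseline-return RMSE.  The other examples cover run simulation and
normalization/debarcoding diagnostics.

## Layout

```
src/cytoglia/      io, panel, synthetic, normalize, debarcode,
                   gate, timecourse, cluster, pipeline
examples/          one narrative script per capability
tests/             unit + property tests and end-to-end checks
docs/methods.md    models, parameters, design choices, limitations
```
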