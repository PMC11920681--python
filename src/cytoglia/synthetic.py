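"""Synthetic CyTOF runs with known ground truth.

The generator emulates the study design: primary microglia (alone or mixed
with astrocytes) stimulated with LPS or Poly(I:C), sampled at ten time
points (0, 5 min, 15 min, 30 min, 1, 2, 4, 8, 24, 48 h), three independent
replicates, all samples palladium-barcoded (3-of-6), pooled, spiked 1:20
with EQ calibration beads, and acquired in one batch with slow sensitivity
drift.  Doublets, dead cells and debris are injected so the clean-up
stages have something to remove, and every event carries a ground-truth
record (sample, population, bead/doublet/dead flags).

Two generators cover the two kinds of planted truth:

:func:`simulate_run`
    Population-level *bulk* dynamics: every microglial cell at time ``t``
    shares the dynamics-implied mean, so replicate-mean fold changes
    recover the planted peak folds (e.g. pERK 16.8-fold under LPS).

:func:`simulate_signaling_states`
    Per-cell *signaling archetypes* (baseline-low, MAPK-high, pSTAT1-high,
    CD40/CD86-high) whose mixture weights shift over the time course —
    the ground truth for the two-round clustering and cluster-abundance
    analytics (e.g. the MAPK archetype peaking at 73% of cells).

The response-curve functional form (log-linear rise to the peak, then
exponential relaxation toward a partially persistent plateau) is a modeling
choice: only the peak amplitudes and timings are constrained by the study,
so downstream checks target amplitude and timing, never the curve shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .debarcode import BarcodeKey, ConfigurationError
from .io import EventTable
from .panel import (
    BARCODE_CHANNELS,
    BEAD_CHANNELS,
    IDENTITY_MARKERS,
    INTERCALATOR_CHANNEL,
    PanelDefinition,
    SIGNALING_MARKERS,
    default_panel,
)

__all__ = [
    "DEFAULT_TIME_POINTS",
    "DEFAULT_SEED",
    "MarkerDynamics",
    "PopulationSpec",
    "SimulationConfig",
    "default_dynamics",
    "default_populations",
    "response_mean",
    "timecourse_config",
    "simulate_run",
    "archetype_profiles",
    "archetype_weights",
    "simulate_signaling_states",
]

#: stimulation time points in hours
DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 5 / 60, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0)

DEFAULT_SEED = 20250108

STIMULI = ("LPS", "PIC")
COMPOSITIONS = ("microglia_only", "mixed")


# ---------------------------------------------------------------------------
# marker dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerDynamics:
    """Planted temporal response of one marker.

    ``baseline`` is the mean resting intensity in ion counts; ``peak_fold``
    the multiplicative response at ``peak_time`` (values < 1 describe
    declining markers such as Cx3CR1); ``persistent_fraction`` the fraction
    of the peak response retained as ``t -> inf``; ``cv`` the per-cell
    lognormal coefficient of variation.
    """

    marker: str
    baseline: float
    peak_fold: float = 1.0
    peak_time: float = 1.0
    onset_time: float = 0.0
    decay_time: float = 2.0
    persistent_fraction: float = 0.0
    cv: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"{self.marker}: baseline must be positive")
        if self.peak_fold <= 0:
            raise ValueError(f"{self.marker}: peak_fold must be positive")
        if self.onset_time > self.peak_time:
            raise ValueError(f"{self.marker}: onset_time must not exceed peak_time")
        if not 0.0 <= self.persistent_fraction <= 1.0:
            raise ValueError(f"{self.marker}: persistent_fraction must be in [0, 1]")


def response_mean(d: MarkerDynamics, t: float) -> float:
    """Mean intensity of marker ``d`` at time ``t`` (hours).

    Piecewise log-linear pulse: flat at ``baseline`` before onset, geometric
    interpolation up to ``baseline * peak_fold`` at the peak, then
    exponential relaxation (time constant ``decay_time``) toward the
    plateau ``baseline * (1 + persistent_fraction * (peak_fold - 1))``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t <= d.onset_time:
        return d.baseline
    if t <= d.peak_time:
        if d.peak_time == d.onset_time:
            return d.baseline * d.peak_fold
        frac = (t - d.onset_time) / (d.peak_time - d.onset_time)
        return d.baseline * d.peak_fold**frac
    plateau = d.baseline * (1.0 + d.persistent_fraction * (d.peak_fold - 1.0))
    peak_value = d.baseline * d.peak_fold
    return plateau + (peak_value - plateau) * math.exp(-(t - d.peak_time) / d.decay_time)


# resting-state mean intensities (ion counts) for the microglial population;
# order-of-magnitude choices except where a planted fold is anchored on them
_MICROGLIA_BASELINES: dict[str, float] = {
    # identity
    "Olig2": 1.0, "CD11b": 150.0, "Fibronectin": 5.0, "GFAP": 2.0, "CD68": 50.0,
    "F480": 60.0, "CD45": 120.0, "Ly6C": 20.0, "Sox2": 3.0, "CD40": 8.0,
    "Galectin1": 30.0, "Cx3CR1": 80.0, "CD86": 8.0,
    # signaling
    "pp38": 12.0, "pERK": 15.0, "pRSK": 10.0, "pCREB": 20.0, "pS6": 8.0,
    "pSTAT1": 6.0, "pSTAT3": 10.0, "pNFkB": 15.0, "pSrc": 25.0, "pAkt": 18.0,
    "pcJun": 8.0, "pgH2AX": 5.0, "bCatenin": 4.0, "Ki67": 10.0,
    "CleavedCaspase3": 3.0,
}


def _dyn(marker: str, fold: float, peak: float, onset: float, decay: float,
         persist: float = 0.0) -> MarkerDynamics:
    return MarkerDynamics(
        marker=marker,
        baseline=_MICROGLIA_BASELINES[marker],
        peak_fold=fold,
        peak_time=peak,
        onset_time=onset,
        decay_time=decay,
        persistent_fraction=persist,
    )


def default_dynamics(stimulus: str, composition: str = "microglia_only"
                     ) -> dict[str, MarkerDynamics]:
    """Planted marker responses for one stimulus/composition.

    Anchored amplitudes: under LPS in microglia-only cultures pERK peaks
    16.8-fold at 15 min and pS6 25-fold at 1 h; under Poly(I:C) the pERK
    peak is blunted to 3.8-fold and delayed to 30 min; CD40 peaks late at
    9-fold (LPS) or 20-fold (Poly(I:C)); astrocyte co-culture caps the CD40
    response at <= 2-fold and halves the mTOR/STAT responses; Cx3CR1
    declines progressively under both stimuli (peak_fold < 1).
    """
    if stimulus not in STIMULI:
        raise ConfigurationError(f"unknown stimulus {stimulus!r}; expected one of {STIMULI}")
    if composition not in COMPOSITIONS:
        raise ConfigurationError(
            f"unknown composition {composition!r}; expected one of {COMPOSITIONS}"
        )
    if stimulus == "LPS":
        base = [
            _dyn("pp38", 12.0, 0.25, 0.03, 1.0, 0.05),
            _dyn("pERK", 16.8, 0.25, 0.03, 0.75, 0.02),
            _dyn("pRSK", 8.0, 0.5, 0.08, 1.0, 0.05),
            _dyn("pCREB", 6.0, 0.5, 0.08, 2.0, 0.10),
            _dyn("pS6", 25.0, 1.0, 0.15, 4.0, 0.10),
            _dyn("pSTAT1", 12.0, 2.0, 0.5, 8.0, 0.15),
            _dyn("pSTAT3", 6.0, 2.0, 0.5, 12.0, 0.30),
            _dyn("pNFkB", 4.0, 0.5, 0.03, 6.0, 0.20),
            _dyn("CD40", 9.0, 24.0, 2.0, 48.0, 0.80),
            _dyn("CD86", 6.0, 24.0, 2.0, 48.0, 0.80),
            _dyn("Ly6C", 3.0, 24.0, 4.0, 48.0, 0.70),
            _dyn("F480", 3.0, 24.0, 4.0, 48.0, 0.70),
            _dyn("Galectin1", 2.5, 24.0, 4.0, 48.0, 0.60),
            _dyn("Ki67", 3.0, 24.0, 8.0, 48.0, 0.50),
            _dyn("Cx3CR1", 0.35, 24.0, 1.0, 48.0, 1.0),
        ]
    else:  # PIC
        base = [
            _dyn("pp38", 3.0, 0.5, 0.08, 1.0, 0.05),
            _dyn("pERK", 3.8, 0.5, 0.08, 1.0, 0.02),
            _dyn("pRSK", 2.5, 0.5, 0.1, 1.0, 0.05),
            _dyn("pCREB", 2.0, 0.5, 0.1, 2.0, 0.10),
            _dyn("pS6", 18.0, 2.0, 0.5, 6.0, 0.10),
            _dyn("pSTAT1", 12.0, 2.0, 0.5, 12.0, 0.35),
            _dyn("pSTAT3", 5.0, 2.0, 0.5, 12.0, 0.35),
            _dyn("pNFkB", 3.0, 0.5, 0.08, 6.0, 0.20),
            _dyn("CD40", 20.0, 24.0, 2.0, 48.0, 0.80),
            _dyn("CD86", 8.0, 24.0, 2.0, 48.0, 0.80),
            _dyn("Galectin1", 2.0, 24.0, 4.0, 48.0, 0.60),
            _dyn("Cx3CR1", 0.4, 24.0, 1.0, 48.0, 1.0),
        ]
    dynamics = {d.marker: d for d in base}

    if composition == "mixed":
        # astrocytes blunt the microglial response: CD40 capped at <= 2-fold,
        # mTOR/CREB/STAT outputs halved, homeostatic Cx3CR1 less depressed;
        # after Poly(I:C) the late reactive state also relaxes back to
        # baseline (low persistence), matching the greater baseline return
        blunted: dict[str, MarkerDynamics] = {}
        for m, d in dynamics.items():
            if m == "CD40":
                d = replace(d, peak_fold=1.8)
            elif m == "CD86":
                d = replace(d, peak_fold=min(d.peak_fold, 2.5))
            elif m in {"pS6", "pCREB", "pSTAT1", "pSTAT3"}:
                d = replace(d, peak_fold=1.0 + 0.5 * (d.peak_fold - 1.0))
            elif m == "Cx3CR1":
                d = replace(d, peak_fold=0.6)
            if stimulus == "PIC" and d.peak_time >= 8.0:
                d = replace(d, persistent_fraction=0.05, decay_time=16.0)
            blunted[m] = d
        dynamics = blunted
    return dynamics


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population of a culture: prevalence and mean marker profile.

    ``responsive`` marks whether the stimulus dynamics act on this
    population (true only for microglia; astrocyte-intrinsic signaling is
    represented as elevated static baselines).
    """

    name: str
    fraction: float
    profile: dict[str, float]
    responsive: bool = False


_ASTROCYTE_PROFILE = {
    **{m: 2.0 for m in IDENTITY_MARKERS},
    "GFAP": 200.0, "Sox2": 60.0, "Fibronectin": 10.0, "CD11b": 2.0, "CD45": 3.0,
    **{m: 5.0 for m in SIGNALING_MARKERS},
    "bCatenin": 80.0, "pAkt": 45.0, "pNFkB": 30.0, "pcJun": 25.0, "pgH2AX": 20.0,
    "pSTAT3": 25.0,
}

_FIBRO_PROFILE = {
    **{m: 2.0 for m in IDENTITY_MARKERS},
    "Fibronectin": 180.0,
    **{m: 4.0 for m in SIGNALING_MARKERS},
}

_DEBRIS_PROFILE = {**{m: 0.5 for m in IDENTITY_MARKERS}, **{m: 0.5 for m in SIGNALING_MARKERS}}


def default_populations(composition: str) -> list[PopulationSpec]:
    """Culture composition: microglia-only cultures carry a small
    fibronectin-high contaminant; mixed cultures add astrocytes."""
    if composition == "microglia_only":
        return [
            PopulationSpec("microglia", 0.97, dict(_MICROGLIA_BASELINES), responsive=True),
            PopulationSpec("fibronectin_hi", 0.03, _FIBRO_PROFILE),
        ]
    if composition == "mixed":
        return [
            PopulationSpec("microglia", 0.70, dict(_MICROGLIA_BASELINES), responsive=True),
            PopulationSpec("astrocyte", 0.22, _ASTROCYTE_PROFILE),
            PopulationSpec("fibronectin_hi", 0.08, _FIBRO_PROFILE),
        ]
    raise ConfigurationError(f"unknown composition {composition!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """One pooled acquisition (a barcoded set of up to 20 samples).

    ``sample_info`` is indexed by sample label with columns ``stimulus``,
    ``composition``, ``time_h``, ``replicate``; the barcode key must cover
    exactly these samples.  ``drift_final`` is the multiplicative
    sensitivity remaining at the end of the run (0.5 = the default 2x
    loss; 1.0 disables drift).  ``bead_fraction`` defaults to 1/21,
    i.e. the 1:20 bead:cell spike-in.
    """

    barcode_key: BarcodeKey
    sample_info: pd.DataFrame
    panel: PanelDefinition = field(default_factory=default_panel)
    events_per_sample: int = 2000
    bead_fraction: float = 1 / 21
    doublet_rate: float = 0.02
    dead_rate: float = 0.03
    drift_final: float = 0.5
    cv: float = 0.3
    barcode_cv: float = 0.25
    seed: int = DEFAULT_SEED
    max_events: int = 5_000_000

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_info.index if s not in self.barcode_key.codes]
        if missing:
            raise ConfigurationError(f"samples without barcode codes: {missing}")
        for rate_name in ("bead_fraction", "doublet_rate", "dead_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0, 1], got {r}")
        if not 0.0 < self.drift_final <= 1.0:
            raise ConfigurationError("drift_final must be in (0, 1]")
        total = self.events_per_sample * len(self.sample_info)
        if total > self.max_events:
            raise ConfigurationError(
                f"{total} events exceed the configured cap of {self.max_events}"
            )


def timecourse_config(
    stimulus: str = "LPS",
    composition: str = "microglia_only",
    replicates=(1,),
    time_points=DEFAULT_TIME_POINTS,
    **kwargs,
) -> SimulationConfig:
    """Config for one barcoded pool: a full time course per replicate.

    With one replicate this is a 10-sample pool; two replicates fill all
    20 codes of the 6-choose-3 key.
    """
    rows = []
    for rep in replicates:
        for t in time_points:
            rows.append(
                {
                    "sample": f"{stimulus}_{composition}_r{rep}_t{t:g}",
                    "stimulus": stimulus,
                    "composition": composition,
                    "time_h": float(t),
                    "replicate": int(rep),
                }
            )
    info = pd.DataFrame(rows).set_index("sample")
    if len(info) > 20:
        raise ConfigurationError(
            f"{len(info)} samples exceed the 20 codes of a 6-choose-3 key"
        )
    key = BarcodeKey.for_samples(info.index, metadata=info)
    return SimulationConfig(barcode_key=key, sample_info=info, **kwargs)


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def simulate_run(config: SimulationConfig) -> tuple[EventTable, pd.DataFrame]:
    """Generate one pooled acquisition with ground truth.

    Returns ``(table, truth)`` where ``truth`` is aligned row-for-row with
    the table and carries: ``sample``, ``stimulus``, ``composition``,
    ``time_h``, ``replicate``, ``population``, ``is_bead``, ``is_doublet``,
    ``is_dead``, and for barcode doublets the second contributing sample
    (``doublet_partner``).

    Construction order: per-sample cells (exact ``events_per_sample``
    counts) -> dead-cell intercalator loss -> pooling and acquisition-order
    shuffle -> doublet formation (channel-wise sums, doubled event length)
    -> bead spike-in -> multiplicative exponential sensitivity drift over
    acquisition order.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    names = [c.name for c in panel.channels]
    col = {n: j for j, n in enumerate(names)}
    markers = panel.markers
    n_chan = len(names)
    instrument = set(panel.names_by_role("instrument"))
    non_instrument = [j for j, n in enumerate(names) if n not in instrument]
    intercal = panel.intercalator

    dyn_cache: dict[tuple[str, str], dict[str, MarkerDynamics]] = {}
    pop_cache: dict[str, list[PopulationSpec]] = {}

    blocks: list[np.ndarray] = []
    truth_rows: list[pd.DataFrame] = []

    for sample, row in config.sample_info.iterrows():
        stim, comp, t = row["stimulus"], row["composition"], float(row["time_h"])
        if (stim, comp) not in dyn_cache:
            dyn_cache[(stim, comp)] = default_dynamics(stim, comp)
        if comp not in pop_cache:
            pop_cache[comp] = default_populations(comp)
        dynamics = dyn_cache[(stim, comp)]
        pops = pop_cache[comp]

        n = config.events_per_sample
        pop_idx = rng.choice(len(pops), size=n, p=[p.fraction for p in pops])
        values = np.zeros((n, n_chan), dtype=np.float64)

        for k, pop in enumerate(pops):
            rows_k = np.flatnonzero(pop_idx == k)
            if rows_k.size == 0:
                continue
            mean = np.zeros(n_chan)
            for m in markers:
                base = pop.profile.get(m, 1.0)
                if pop.responsive and m in dynamics:
                    mean[col[m]] = response_mean(dynamics[m], t)
                else:
                    mean[col[m]] = base
            noise = _lognormal_factor(rng, config.cv, (rows_k.size, len(markers)))
            marker_cols = [col[m] for m in markers]
            values[np.ix_(rows_k, marker_cols)] = mean[marker_cols] * noise

        # palladium barcode channels: on-code high, off-code near zero
        code = config.barcode_key.codes[sample]
        for ch in config.barcode_key.channels:
            j = col[ch]
            if ch in code:
                values[:, j] = 150.0 * _lognormal_factor(rng, config.barcode_cv, n)
            else:
                values[:, j] = rng.exponential(1.5, size=n)

        # DNA intercalator: nucleated events high; debris low; dead cells reduced
        inter = 600.0 * _lognormal_factor(rng, 0.2, n)
        debris = np.array([pops[k].name == "debris" for k in pop_idx])
        inter[debris] *= 0.02
        is_dead = rng.random(n) < config.dead_rate
        inter[is_dead] *= 0.08
        values[:, col[intercal]] = inter
        if "CleavedCaspase3" in col:
            values[is_dead, col["CleavedCaspase3"]] *= 5.0

        # bead channels on cells: low environmental background
        for ch in BEAD_CHANNELS:
            values[:, col[ch]] = rng.exponential(0.8, size=n)

        values[:, col["Event_length"]] = np.clip(rng.normal(30.0, 2.5, n), 12.0, None)
        values[:, col["Center"]] = rng.normal(600.0, 40.0, n)

        blocks.append(values)
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "stimulus": stim,
                    "composition": comp,
                    "time_h": t,
                    "replicate": int(row["replicate"]),
                    "population": [pops[k].name for k in pop_idx],
                    "is_bead": False,
                    "is_doublet": False,
                    "is_dead": is_dead,
                    "doublet_partner": None,
                }
            )
        )

    values = np.concatenate(blocks, axis=0)
    truth = pd.concat(truth_rows, ignore_index=True)
    n_cells = len(values)

    # acquisition order is randomized before artifact injection
    perm = rng.permutation(n_cells)
    values = values[perm]
    truth = truth.iloc[perm].reset_index(drop=True)

    # doublets: merge adjacent pairs drawn across the pooled stream so a
    # fraction of them joins two differently barcoded samples
    n_doublets = int(round(config.doublet_rate * n_cells))
    if n_doublets:
        chosen = rng.choice(n_cells, size=2 * n_doublets, replace=False)
        a, b = chosen[:n_doublets], chosen[n_doublets:]
        merged = values[a].copy()
        merged[:, non_instrument] += values[b][:, non_instrument]
        merged[:, col["Event_length"]] = (
            values[a][:, col["Event_length"]] + values[b][:, col["Event_length"]]
        )
        merged[:, col["Center"]] = 0.5 * (
            values[a][:, col["Center"]] + values[b][:, col["Center"]]
        )
        values[a] = merged
        truth.loc[a, "is_doublet"] = True
        truth.loc[a, "doublet_partner"] = truth.loc[b, "sample"].to_numpy()
        keep = np.setdiff1d(np.arange(n_cells), b)
        values = values[keep]
        truth = truth.iloc[keep].reset_index(drop=True)

    # calibration-bead spike-in
    n_beads = rng.binomial(n_cells, config.bead_fraction)
    if n_beads:
        bead = np.zeros((n_beads, n_chan))
        for m in markers:
            bead[:, col[m]] = rng.exponential(0.5, size=n_beads)
        for ch in BARCODE_CHANNELS:
            bead[:, col[ch]] = rng.exponential(0.5, size=n_beads)
        for ch in BEAD_CHANNELS:
            bead[:, col[ch]] = 4000.0 * _lognormal_factor(rng, 0.1, n_beads)
        bead[:, col[intercal]] = rng.exponential(1.0, size=n_beads)
        bead[:, col["Event_length"]] = np.clip(rng.normal(20.0, 2.0, n_beads), 10.0, None)
        bead[:, col["Center"]] = rng.normal(600.0, 40.0, n_beads)
        bead_truth = pd.DataFrame(
            {
                "sample": None, "stimulus": None, "composition": None,
                "time_h": np.nan, "replicate": -1, "population": "bead",
                "is_bead": True, "is_doublet": False, "is_dead": False,
                "doublet_partner": None,
            },
            index=range(n_beads),
        )
        n_total = len(values) + n_beads
        bead_pos = np.zeros(n_total, dtype=bool)
        bead_pos[rng.choice(n_total, size=n_beads, replace=False)] = True
        combined = np.empty((n_total, n_chan))
        combined[~bead_pos] = values
        combined[bead_pos] = bead
        values = combined
        order = np.empty(n_total, dtype=int)
        order[~bead_pos] = np.arange(len(truth))
        order[bead_pos] = len(truth) + np.arange(n_beads)
        truth = pd.concat([truth, bead_truth], ignore_index=True).iloc[order]
        truth = truth.reset_index(drop=True)

    # smooth multiplicative sensitivity drift over acquisition order
    if config.drift_final < 1.0:
        n_total = len(values)
        factor = config.drift_final ** (np.arange(n_total) / max(n_total - 1, 1))
        values[:, non_instrument] *= factor[:, None]

    truth["acquisition_index"] = np.arange(len(values))
    table = EventTable(values.astype(np.float32), list(panel.channels))
    table.log_stage(
        f"simulate_run:{len(config.sample_info)}samples:seed={config.seed}"
    )
    return table, truth


# ---------------------------------------------------------------------------
# signaling-archetype simulation (clustering ground truth)
# ---------------------------------------------------------------------------

#: per-archetype marker fold over the microglial baseline
_ARCHETYPE_FOLDS: dict[str, dict[str, float]] = {
    "baseline": {},
    "mapk": {"pERK": 18.0, "pp38": 14.0, "pRSK": 8.0, "pCREB": 6.0},
    "pstat1": {"pSTAT1": 14.0, "pSTAT3": 4.0},
    "cd40": {"CD40": 10.0, "CD86": 7.0, "pSTAT3": 5.0, "pNFkB": 4.0, "pSrc": 3.0},
}

ARCHETYPES = tuple(_ARCHETYPE_FOLDS)

# mixture weight of each non-baseline archetype at the ten design time
# points; the baseline archetype takes the remainder.  Prevalence anchors:
# the MAPK archetype peaks at 73% of cells (LPS, 15 min); the late
# CD40/CD86 archetype holds 56.4% / 53.4% / 39.8% / 3.68% of cells at 48 h
# in LPS-micro / LPS-mixed / PIC-micro / PIC-mixed respectively.
_WEIGHT_TABLES: dict[tuple[str, str], dict[str, tuple[float, ...]]] = {
    ("LPS", "microglia_only"): {
        "mapk":   (0.0, 0.10, 0.73, 0.25, 0.08, 0.02, 0.0, 0.0, 0.0, 0.0),
        "pstat1": (0.0, 0.0, 0.0, 0.05, 0.25, 0.63, 0.45, 0.20, 0.05, 0.02),
        "cd40":   (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.10, 0.35, 0.70, 0.564),
    },
    ("PIC", "microglia_only"): {
        "mapk":   (0.0, 0.02, 0.15, 0.45, 0.20, 0.05, 0.0, 0.0, 0.0, 0.0),
        "pstat1": (0.0, 0.0, 0.0, 0.02, 0.20, 0.80, 0.60, 0.35, 0.10, 0.05),
        "cd40":   (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.08, 0.30, 0.70, 0.398),
    },
    ("LPS", "mixed"): {
        "mapk":   (0.0, 0.08, 0.60, 0.20, 0.06, 0.02, 0.0, 0.0, 0.0, 0.0),
        "pstat1": (0.0, 0.0, 0.0, 0.04, 0.20, 0.50, 0.35, 0.15, 0.04, 0.02),
        "cd40":   (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.08, 0.30, 0.65, 0.534),
    },
    ("PIC", "mixed"): {
        "mapk":   (0.0, 0.02, 0.10, 0.35, 0.15, 0.04, 0.0, 0.0, 0.0, 0.0),
        "pstat1": (0.0, 0.0, 0.0, 0.02, 0.15, 0.65, 0.45, 0.25, 0.06, 0.02),
        "cd40":   (0.0, 0.0, 0.0, 0.0, 0.0, 0.01, 0.05, 0.25, 0.55, 0.0368),
    },
}


def archetype_profiles() -> dict[str, dict[str, float]]:
    """Mean marker profile (ion counts) of each signaling archetype."""
    out = {}
    for name, folds in _ARCHETYPE_FOLDS.items():
        profile = dict(_MICROGLIA_BASELINES)
        for m, f in folds.items():
            profile[m] = profile[m] * f
        out[name] = profile
    return out


def archetype_weights(stimulus: str, composition: str, t: float) -> dict[str, float]:
    """Archetype mixture weights at time ``t`` (linear interpolation
    between the design time points)."""
    key = (stimulus, composition)
    if key not in _WEIGHT_TABLES:
        raise ConfigurationError(f"no archetype weights for {key}")
    grid = np.asarray(DEFAULT_TIME_POINTS)
    weights = {
        name: float(np.interp(t, grid, vals)) for name, vals in _WEIGHT_TABLES[key].items()
    }
    weights["baseline"] = max(0.0, 1.0 - sum(weights.values()))
    return weights


def simulate_signaling_states(
    stimulus: str = "LPS",
    composition: str = "microglia_only",
    n_per_sample: int = 200,
    replicates: int = 3,
    time_points=DEFAULT_TIME_POINTS,
    cv: float = 0.35,
    seed: int = DEFAULT_SEED,
) -> tuple[EventTable, pd.DataFrame]:
    """Microglial events drawn from the 4-archetype mixture.

    Events are post-clean-up microglia (identity + signaling channels only);
    sample metadata (stimulus, composition, time_h, replicate) is attached
    as annotations, and the returned ``truth`` frame carries each cell's
    ground-truth ``archetype``.
    """
    rng = np.random.default_rng(seed)
    panel = default_panel()
    marker_channels = [c for c in panel.channels if c.role in ("identity", "signaling")]
    names = [c.name for c in marker_channels]
    profiles = archetype_profiles()
    arch_means = np.array([[profiles[a][m] for m in names] for a in ARCHETYPES])

    values_blocks, meta_rows, arch_labels = [], [], []
    for rep in range(1, replicates + 1):
        for t in time_points:
            w = archetype_weights(stimulus, composition, t)
            p = np.array([w[a] for a in ARCHETYPES])
            p = p / p.sum()
            draws = rng.choice(len(ARCHETYPES), size=n_per_sample, p=p)
            mean = arch_means[draws]
            noise = _lognormal_factor(rng, cv, mean.shape)
            values_blocks.append(mean * noise)
            arch_labels.extend(ARCHETYPES[k] for k in draws)
            meta_rows.append(
                pd.DataFrame(
                    {
                        "sample": f"{stimulus}_{composition}_r{rep}_t{t:g}",
                        "stimulus": stimulus,
                        "composition": composition,
                        "time_h": float(t),
                        "replicate": rep,
                    },
                    index=range(n_per_sample),
                )
            )

    values = np.concatenate(values_blocks, axis=0).astype(np.float32)
    meta = pd.concat(meta_rows, ignore_index=True)
    table = EventTable(values, marker_channels, annotations=meta)
    table.log_stage(
        f"simulate_signaling_states:{stimulus}:{composition}:seed={seed}"
    )
    truth = meta.copy()
    truth["archetype"] = arch_labels
    return table, truth
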