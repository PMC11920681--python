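"""Calibration-bead signal-drift normalization.

Mass cytometer sensitivity decays slowly over a long acquisition.  EQ
four-element calibration beads (Ce/Eu/Ho/Lu) spiked 1:20 into every sample
provide a constant reference: windowed medians of the bead channels trace
the drift, and dividing every event by the interpolated local-to-global
median ratio flattens it.

The procedure: classify bead events (high in *all* bead channels), compute
per-window per-bead-channel medians over the acquisition order, aggregate
the per-channel reference/local ratios into one scalar factor per window
(geometric mean — drift is mass-channel-wide), linearly interpolate
between window centers, clamp to [0.1, 10], and multiply every
non-instrument channel.  Beads are then dropped from the event stream;
a residual-cerium gate downstream catches stragglers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .debarcode import ConfigurationError
from .io import EventTable

__all__ = [
    "BeadModel",
    "NormalizationError",
    "identify_beads",
    "fit_drift",
    "apply_normalization",
    "drop_beads",
    "normalize_run",
]


class NormalizationError(RuntimeError):
    """Raised when bead statistics are insufficient to fit a drift model."""


@dataclass
class BeadModel:
    """Fitted drift model.

    ``window_medians`` holds one row per bead window (columns: window
    center in acquisition index plus one column per bead channel);
    ``reference_medians`` the global per-channel bead medians; ``centers``
    and ``factors`` the interpolation knots of the scalar correction.
    """

    bead_index: np.ndarray
    window_size: int
    bead_channels: list[str]
    window_medians: pd.DataFrame
    reference_medians: pd.Series
    centers: np.ndarray
    factors: np.ndarray
    n_events: int = 0

    def correction_at(self, positions: np.ndarray) -> np.ndarray:
        """Per-event scalar correction factor, clamped to [0.1, 10]."""
        f = np.interp(positions, self.centers, self.factors)
        return np.clip(f, 0.1, 10.0)

    def report(self) -> pd.DataFrame:
        """Drift report: window center, per-channel medians, scalar factor."""
        return self.window_medians.copy()


def _bimodal_threshold(x: np.ndarray) -> float:
    """Split a bimodal intensity channel at the midpoint of a 2-means fit
    on arcsinh-transformed values."""
    t = np.arcsinh(np.asarray(x, dtype=np.float64) / 5.0).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(t)
    lo, hi = np.sort(km.cluster_centers_.ravel())
    return float(5.0 * np.sinh(0.5 * (lo + hi)))


def identify_beads(table: EventTable, threshold_quantile: float | None = None) -> np.ndarray:
    """Indices of calibration-bead events.

    A bead must be high in *all* bead channels (conjunction rule: cells
    with incidental cerium background in one channel are not beads).  Per
    channel the default threshold comes from a bimodal split of the
    intensity distribution; ``threshold_quantile`` overrides it with a
    plain quantile cut per channel.

    Raises
    ------
    ConfigurationError
        If the panel declares fewer than two bead channels.
    NormalizationError
        If fewer than 50 bead events are found (too few to fit drift).
    """
    bead_channels = table.channels_by_role("bead")
    if len(bead_channels) < 2:
        raise ConfigurationError(
            f"bead identification needs >= 2 bead-role channels, found {len(bead_channels)}"
        )
    mask = np.ones(table.n_events, dtype=bool)
    for ch in bead_channels:
        x = table.data(ch)
        if threshold_quantile is not None:
            thr = np.quantile(x, threshold_quantile)
        else:
            thr = _bimodal_threshold(x)
        mask &= x > thr
    idx = np.flatnonzero(mask)
    if len(idx) < 50:
        raise NormalizationError(
            f"only {len(idx)} bead events found; >= 50 required — normalization refused"
        )
    return idx


def fit_drift(table: EventTable, beads: np.ndarray, window_size: int = 500) -> BeadModel:
    """Fit the windowed-median drift model on the bead events.

    Beads are walked in acquisition order in consecutive windows of
    ``window_size`` events (the final, shorter window is merged into its
    neighbor); per window the median of each bead channel is computed.
    The scalar factor at a window is the geometric mean over channels of
    ``reference_median / window_median``; windows with a zero median in
    any channel are excluded and bridged by interpolation.
    """
    beads = np.sort(np.asarray(beads))
    if len(beads) < 50:
        raise NormalizationError(f"need >= 50 bead events to fit drift, got {len(beads)}")
    window_size = int(window_size)
    if window_size < 10:
        raise ValueError("window_size must be >= 10 bead events")
    bead_channels = table.channels_by_role("bead")
    sub = np.stack([table.data(ch)[beads] for ch in bead_channels], axis=1).astype(np.float64)

    n_windows = max(1, len(beads) // window_size)
    edges = np.linspace(0, len(beads), n_windows + 1).astype(int)
    centers, medians = [], []
    for w in range(n_windows):
        sl = slice(edges[w], edges[w + 1])
        med = np.median(sub[sl], axis=0)
        if np.any(med <= 0):
            continue  # degenerate window; neighbors will be interpolated
        centers.append(float(np.mean(beads[sl])))
        medians.append(med)
    if not centers:
        raise NormalizationError("all bead windows had a zero median; cannot fit drift")
    med_arr = np.asarray(medians)
    reference = np.median(sub, axis=0)
    with np.errstate(divide="ignore"):
        ratio = reference[None, :] / med_arr
    factors = np.exp(np.mean(np.log(ratio), axis=1))

    # extend the knots to the run boundaries by log-linear extrapolation so
    # events before the first / after the last window center are not held
    # at a constant (wrong) factor
    centers_arr = np.asarray(centers, dtype=float)
    factors_arr = factors
    if len(centers_arr) >= 2:
        logf = np.log(factors_arr)
        lo_slope = (logf[1] - logf[0]) / (centers_arr[1] - centers_arr[0])
        hi_slope = (logf[-1] - logf[-2]) / (centers_arr[-1] - centers_arr[-2])
        first = np.exp(logf[0] - lo_slope * centers_arr[0])
        last = np.exp(logf[-1] + hi_slope * (table.n_events - 1 - centers_arr[-1]))
        centers_arr = np.concatenate([[0.0], centers_arr, [table.n_events - 1.0]])
        factors_arr = np.concatenate([[first], factors_arr, [last]])

    window_medians = pd.DataFrame(med_arr, columns=bead_channels)
    window_medians.insert(0, "center", centers)
    window_medians["factor"] = factors
    return BeadModel(
        bead_index=beads,
        window_size=window_size,
        bead_channels=list(bead_channels),
        window_medians=window_medians,
        reference_medians=pd.Series(reference, index=bead_channels),
        centers=centers_arr,
        factors=factors_arr,
        n_events=table.n_events,
    )


def apply_normalization(table: EventTable, model: BeadModel) -> EventTable:
    """Multiply every non-instrument channel by the event's drift factor.

    Instrument parameters (event length, center) are physical event-shape
    summaries, not mass-channel intensities, and are left untouched.
    Zero intensities are preserved exactly (multiplication by a finite
    factor).
    """
    if model.n_events and model.n_events != table.n_events:
        raise ValueError(
            f"model was fitted on {model.n_events} events but table has {table.n_events}"
        )
    factor = model.correction_at(np.arange(table.n_events, dtype=np.float64))
    out = table.copy()
    targets = [j for j, c in enumerate(out.channels) if c.role != "instrument"]
    out.values[:, targets] = (out.values[:, targets] * factor[:, None]).astype(np.float32)
    out.log_stage(f"apply_normalization:window={model.window_size}")
    return out


def drop_beads(table: EventTable, beads: np.ndarray) -> EventTable:
    """Remove the identified bead events from the stream."""
    mask = np.ones(table.n_events, dtype=bool)
    mask[np.asarray(beads)] = False
    out = table.subset(mask)
    out.log_stage(f"drop_beads:{len(beads)}removed")
    return out


def normalize_run(
    table: EventTable,
    window_size: int = 500,
    threshold_quantile: float | None = None,
    remove_beads: bool = True,
) -> tuple[EventTable, BeadModel, np.ndarray]:
    """Convenience wrapper: identify beads, fit drift, correct, drop beads.

    Returns ``(corrected_table, model, kept_mask)`` where ``kept_mask`` is
    a boolean mask over the *input* events (False for removed beads), so
    callers can subset aligned ground-truth tables the same way.
    """
    beads = identify_beads(table, threshold_quantile=threshold_quantile)
    model = fit_drift(table, beads, window_size=window_size)
    corrected = apply_normalization(table, model)
    kept = np.ones(table.n_events, dtype=bool)
    if remove_beads:
        kept[beads] = False
        corrected = corrected.subset(kept)
    return corrected, model, kept


def check_flatness(table: EventTable, model: BeadModel, window_size: int | None = None) -> float:
    """Maximum relative deviation of windowed bead medians from their
    global median, after correction — the normalization quality metric.

    Refits windowed medians on the corrected table restricted to the
    model's bead events and returns ``max |median_w / median_global - 1|``
    over windows and bead channels.
    """
    ws = window_size or model.window_size
    beads = model.bead_index
    sub = np.stack(
        [table.data(ch)[beads] for ch in model.bead_channels], axis=1
    ).astype(np.float64)
    n_windows = max(1, len(beads) // ws)
    edges = np.linspace(0, len(beads), n_windows + 1).astype(int)
    global_med = np.median(sub, axis=0)
    worst = 0.0
    for w in range(n_windows):
        med = np.median(sub[edges[w]: edges[w + 1]], axis=0)
        worst = max(worst, float(np.max(np.abs(med / global_med - 1.0))))
    return worst

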