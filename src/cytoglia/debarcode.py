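"""Combinatorial palladium debarcoding (6-choose-3 scheme).

Pooled samples are tagged before acquisition with unique combinations of
three out of six palladium isotopes, so each event should be positive in
exactly the three channels of its sample's code.  Deconvolution ranks each
event's rescaled barcode intensities, takes the top three channels as the
candidate code, and assigns the event to the matching sample if the
candidate is in the key.

Three per-event quality statistics support downstream clean-up gating:

``separation``
    Margin between the lowest expected-positive and the highest
    expected-negative rescaled barcode channel (3rd minus 4th ranked
    value); near-zero separation means an ambiguous assignment.
``mahalanobis``
    Distance of the event within its assigned sample's 6-channel raw
    barcode distribution; outliers are likely mis-assignments.
``bc_neg``
    Sum of the three *raw* palladium intensities expected to be zero under
    the assigned code.  Multi-cell events that merge two differently
    barcoded cells light up extra palladium channels, so high bc_neg flags
    barcode doublets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import EventTable
from .panel import BARCODE_CHANNELS

__all__ = [
    "BarcodeKey",
    "ConfigurationError",
    "rescale_barcode_channels",
    "assign_barcodes",
    "filter_assignments",
]


class ConfigurationError(ValueError):
    """Raised when inputs are structurally unusable (wrong channels, empty key, ...)."""


@dataclass
class BarcodeKey:
    """Sample labels mapped to 3-subsets of the six barcode channels.

    ``metadata`` optionally carries per-sample design columns
    (stimulus, composition, time_h, replicate) keyed by sample label.
    """

    codes: dict[str, frozenset]
    channels: tuple = tuple(BARCODE_CHANNELS)
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) != 6:
            raise ConfigurationError(f"expected 6 barcode channels, got {len(self.channels)}")
        if len(self.codes) > 20:
            raise ConfigurationError("a 6-choose-3 key admits at most 20 codes")
        chanset = set(self.channels)
        seen: dict[frozenset, str] = {}
        for sample, code in self.codes.items():
            code = frozenset(code)
            if len(code) != 3 or not code <= chanset:
                raise ConfigurationError(
                    f"code for sample {sample!r} must be a 3-subset of the barcode channels"
                )
            if code in seen:
                raise ConfigurationError(
                    f"samples {seen[code]!r} and {sample!r} share a barcode code"
                )
            seen[code] = sample
            self.codes[sample] = code

    @classmethod
    def full(cls, channels=BARCODE_CHANNELS, labels=None) -> "BarcodeKey":
        """Key over all 20 3-subsets, in lexicographic channel order."""
        combos = list(combinations(channels, 3))
        if labels is None:
            labels = [f"S{i + 1:02d}" for i in range(len(combos))]
        if len(labels) > len(combos):
            raise ConfigurationError("more labels than available codes")
        return cls({lab: frozenset(c) for lab, c in zip(labels, combos)}, tuple(channels))

    @classmethod
    def for_samples(cls, labels, channels=BARCODE_CHANNELS,
                    metadata: pd.DataFrame | None = None) -> "BarcodeKey":
        """Assign the first ``len(labels)`` codes (lexicographic) to ``labels``."""
        key = cls.full(channels, labels=list(labels))
        key.metadata = metadata
        return key

    def samples(self) -> list[str]:
        return list(self.codes)

    def code_lookup(self) -> dict[frozenset, str]:
        return {code: sample for sample, code in self.codes.items()}


def rescale_barcode_channels(table: EventTable, channels=None) -> np.ndarray:
    """Event x 6 matrix of barcode intensities rescaled to [0, 1].

    Each channel is first divided by its robust positive span (95th
    percentile of its positive values), then each event's six values are
    divided by the event maximum so the top channel reads 1.  All-zero
    events stay all-zero (they are unassignable).  Both steps are monotone
    per channel, so the within-event channel rank order is preserved.
    """
    if channels is None:
        channels = table.channels_by_role("barcode")
    if len(channels) != 6:
        raise ConfigurationError(f"expected 6 barcode channels, found {len(channels)}")
    raw = np.stack([table.data(c) for c in channels], axis=1).astype(np.float64)
    scaled = np.empty_like(raw)
    for j, name in enumerate(channels):
        pos = raw[:, j][raw[:, j] > 0]
        if pos.size == 0:
            raise ConfigurationError(f"barcode channel {name!r} is identically zero")
        span = np.percentile(pos, 95)
        if span <= 0:
            span = pos.max()
        scaled[:, j] = raw[:, j] / span
    row_max = scaled.max(axis=1, keepdims=True)
    nonzero = row_max[:, 0] > 0
    scaled[nonzero] /= row_max[nonzero]
    return scaled


def _mahalanobis_by_sample(raw: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Per-event Mahalanobis distance within its assigned sample's barcode cloud."""
    out = np.zeros(len(raw))
    for sample in pd.unique(samples):
        if sample is None or (isinstance(sample, float) and np.isnan(sample)):
            continue
        idx = np.flatnonzero(samples == sample)
        if len(idx) < 7:
            warnings.warn(
                f"sample {sample!r} has {len(idx)} events; Mahalanobis distance set to 0",
                stacklevel=3,
            )
            continue
        sub = raw[idx]
        mu = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False)
        cov += np.eye(cov.shape[0]) * (1e-6 * np.trace(cov) / cov.shape[0] + 1e-12)
        inv = np.linalg.inv(cov)
        diff = sub - mu
        out[idx] = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff))
    return out


def assign_barcodes(table: EventTable, key: BarcodeKey) -> pd.DataFrame:
    """Deconvolute each event to a sample via the 3-of-6 code ranking.

    Returns a DataFrame aligned with the table's events:

    ``bc_sample``
        Assigned sample label, or ``None`` for unassigned events (candidate
        code absent from the key, or all-zero barcode signal).
    ``bc_separation``
        3rd-minus-4th ranked rescaled value (0 on ties or all-zero events).
    ``bc_mahalanobis``
        Within-sample raw-channel Mahalanobis distance (0 if unassigned).
    ``bc_neg``
        Sum of the raw intensities of the three off-code channels
        (NaN if unassigned).
    """
    channels = [c for c in key.channels]
    for c in channels:
        table.channel_index(c)  # raises KeyError with the channel name
    rescaled = rescale_barcode_channels(table, channels)
    raw = np.stack([table.data(c) for c in channels], axis=1).astype(np.float64)
    n = len(rescaled)

    order = np.argsort(-rescaled, axis=1, kind="stable")
    ranked = np.take_along_axis(rescaled, order, axis=1)
    separation = ranked[:, 2] - ranked[:, 3]
    all_zero = rescaled.max(axis=1) == 0
    separation[all_zero] = 0.0

    lookup = key.code_lookup()
    chan_arr = np.array(channels)
    samples = np.empty(n, dtype=object)
    bc_neg = np.full(n, np.nan)
    top3 = order[:, :3]
    # group identical candidate codes to avoid a python-level loop per event
    code_ids = np.sort(top3, axis=1)
    uniq, inverse = np.unique(code_ids, axis=0, return_inverse=True)
    for u, cols in enumerate(uniq):
        members = np.flatnonzero(inverse == u)
        code = frozenset(chan_arr[cols])
        sample = lookup.get(code)
        if sample is None:
            continue
        off = [j for j in range(6) if j not in set(cols)]
        usable = members[~all_zero[members]]
        samples[usable] = sample
        bc_neg[usable] = raw[np.ix_(usable, off)].sum(axis=1)

    mahal = _mahalanobis_by_sample(raw, samples)
    return pd.DataFrame(
        {
            "bc_sample": samples,
            "bc_separation": separation,
            "bc_mahalanobis": mahal,
            "bc_neg": bc_neg,
        }
    )


def filter_assignments(
    assignments: pd.DataFrame,
    min_separation: float = 0.3,
    max_mahalanobis: float = 30.0,
    max_bc_neg: float | str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Retain confidently debarcoded events.

    An event survives when it has a sample assignment, separation >=
    ``min_separation``, Mahalanobis <= ``max_mahalanobis``, and (when the
    optional bc_neg cut is enabled) bc_neg <= ``max_bc_neg``.  Pass
    ``max_bc_neg="p95"`` for a per-sample 95th-percentile cut, a float for
    a global cut, or ``None`` (default) to skip it — the barcode-negativity
    parameter is normally consumed later, during clean-up gating.

    Returns ``(retained_indices, attrition)`` where ``attrition`` counts,
    per criterion, the events removed by that criterion alone.
    """
    assigned = assignments["bc_sample"].notna().to_numpy()
    sep_ok = assignments["bc_separation"].to_numpy() >= min_separation
    mah_ok = assignments["bc_mahalanobis"].to_numpy() <= max_mahalanobis
    if max_bc_neg is None:
        neg_ok = np.ones(len(assignments), dtype=bool)
    elif max_bc_neg == "p95":
        neg_ok = np.ones(len(assignments), dtype=bool)
        bc = assignments["bc_neg"]
        for sample, grp in assignments.loc[assigned].groupby("bc_sample"):
            cut = grp["bc_neg"].quantile(0.95)
            bad = assigned & (assignments["bc_sample"] == sample).to_numpy() & (bc > cut).to_numpy()
            neg_ok[bad] = False
    else:
        neg_ok = ~(assignments["bc_neg"].to_numpy() > float(max_bc_neg))

    keep = assigned & sep_ok & mah_ok & neg_ok
    attrition = pd.DataFrame(
        {
            "criterion": ["unassigned", "low_separation", "high_mahalanobis", "high_bc_neg"],
            "removed": [
                int((~assigned).sum()),
                int((assigned & ~sep_ok).sum()),
                int((assigned & ~mah_ok).sum()),
                int((assigned & ~neg_ok).sum()),
            ],
        }
    )
    if not keep.any():
        raise ConfigurationError(
            "debarcode filter retained zero events; per-criterion attrition:\n"
            + attrition.to_string(index=False)
        )
    return np.flatnonzero(keep), attrition
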