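"""Bulk per-marker time-course statistics.

After clean-up gating, each sample (stimulus x composition x time point x
replicate) is summarized by its arithmetic mean raw intensity per marker.
Responses are reported as fold changes over the matched vehicle — the
t = 0 sample of the same condition and replicate — with log2 fold changes
averaged across replicates for heatmap display, and the signed maximal
divergence between two conditions summarizing where their time courses
differ most.

Fold changes are computed on raw (bead-normalized, untransformed) means:
the reported magnitudes (a 16.8- or 25-fold induction) are ratios of ion
counts, not of arcsinh-transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventTable

__all__ = [
    "TimecourseMatrix",
    "marker_means",
    "log2_fold_change",
    "max_divergence",
]

SAMPLE_COLS = ("stimulus", "composition", "time_h", "replicate")

LOW_CONFIDENCE_N = 50


@dataclass
class TimecourseMatrix:
    """Marker x time-point response matrices for one condition.

    ``log2fc`` and ``linear_fold`` hold per-replicate values (long
    format); ``mean_log2fc`` is the replicate-averaged marker x time
    matrix (the heatmap layer).  ``metadata`` records the condition
    labels.  Invariant: the t = 0 column of every fold-change layer is
    identically 0 (log2) / 1 (linear).
    """

    log2fc: pd.DataFrame
    linear_fold: pd.DataFrame
    mean_log2fc: pd.DataFrame
    mean_linear_fold: pd.DataFrame
    metadata: dict

    @property
    def markers(self) -> list[str]:
        return list(self.mean_log2fc.index)

    @property
    def time_points(self) -> list[float]:
        return list(self.mean_log2fc.columns)

    def peak_linear_fold(self, marker: str) -> tuple[float, float]:
        """(time, fold) of the maximal absolute replicate-mean log2 response."""
        row = self.mean_log2fc.loc[marker]
        t = row.abs().idxmax()
        return float(t), float(self.mean_linear_fold.loc[marker, t])


def marker_means(
    table: EventTable,
    markers: list[str] | None = None,
    sample_cols=SAMPLE_COLS,
) -> pd.DataFrame:
    """Per-sample arithmetic mean raw intensity per marker.

    Events must carry the sample design columns as annotations.  Returns a
    long-format frame (one row per sample) with one column per marker,
    plus ``n_events`` and a ``low_confidence`` flag for samples with fewer
    than 50 events.  Empty strata simply do not appear (missing, never
    zero).
    """
    missing = [c for c in sample_cols if c not in table.annotations.columns]
    if missing:
        raise ValueError(f"events lack sample annotations: {missing}")
    if markers is None:
        markers = table.marker_names()
    mat = pd.DataFrame(
        {m: table.data(m) for m in markers}, index=table.annotations.index
    )
    grouped = pd.concat([table.annotations[list(sample_cols)], mat], axis=1).groupby(
        list(sample_cols), dropna=False, observed=True
    )
    means = grouped[markers].mean()
    means["n_events"] = grouped.size()
    means["low_confidence"] = means["n_events"] < LOW_CONFIDENCE_N
    return means.reset_index()


def log2_fold_change(
    means: pd.DataFrame,
    markers: list[str] | None = None,
    group_cols=("stimulus", "composition"),
) -> dict[tuple, TimecourseMatrix]:
    """Vehicle-normalized fold changes per condition.

    For every (stimulus, composition) group and replicate, each marker's
    mean at time ``t`` is divided by the same replicate's t = 0 (vehicle)
    mean; the log2 ratio is averaged across replicates (average of log2
    ratios, not log2 of the average ratio).  Markers whose vehicle mean is
    zero are excluded with a diagnostic attached to the result metadata.
    """
    if markers is None:
        markers = [
            c for c in means.columns
            if c not in set(group_cols) | {"time_h", "replicate", "n_events", "low_confidence"}
        ]
    out: dict[tuple, TimecourseMatrix] = {}
    for cond, grp in means.groupby(list(group_cols), observed=True):
        cond = cond if isinstance(cond, tuple) else (cond,)
        long_rows = []
        excluded: set[str] = set()
        for rep, sub in grp.groupby("replicate"):
            sub = sub.sort_values("time_h")
            vehicle = sub[np.isclose(sub["time_h"], 0.0)]
            if vehicle.empty:
                raise ValueError(f"condition {cond}, replicate {rep}: no t = 0 vehicle sample")
            v = vehicle.iloc[0]
            for m in markers:
                if not v[m] > 0:
                    excluded.add(m)
                    continue
                for _, row in sub.iterrows():
                    ratio = row[m] / v[m]
                    long_rows.append(
                        {
                            "marker": m,
                            "replicate": rep,
                            "time_h": float(row["time_h"]),
                            "linear_fold": ratio,
                            "log2fc": np.log2(ratio),
                        }
                    )
        long = pd.DataFrame(long_rows)
        mean_log2 = long.pivot_table(
            index="marker", columns="time_h", values="log2fc", aggfunc="mean"
        )
        mean_lin = 2.0 ** mean_log2  # geometric replicate mean, consistent with the log2 layer
        out[cond] = TimecourseMatrix(
            log2fc=long.pivot_table(
                index=["marker", "replicate"], columns="time_h", values="log2fc"
            ),
            linear_fold=long.pivot_table(
                index=["marker", "replicate"], columns="time_h", values="linear_fold"
            ),
            mean_log2fc=mean_log2,
            mean_linear_fold=mean_lin,
            metadata={
                "condition": cond,
                "excluded_zero_vehicle": sorted(excluded),
            },
        )
    return out


def max_divergence(a: TimecourseMatrix, b: TimecourseMatrix) -> pd.Series:
    """Signed maximal difference of replicate-mean log2 fold changes.

    Per marker, the value of ``a - b`` at the time point maximizing
    ``|a - b|`` (positive = greater response in ``a``).  Marker and time
    axes must match.
    """
    if list(a.mean_log2fc.index) != list(b.mean_log2fc.index) or list(
        a.mean_log2fc.columns
    ) != list(b.mean_log2fc.columns):
        bad_markers = sorted(
            set(a.mean_log2fc.index).symmetric_difference(b.mean_log2fc.index)
        )
        bad_times = sorted(
            set(a.mean_log2fc.columns).symmetric_difference(b.mean_log2fc.columns)
        )
        raise ValueError(
            f"axis mismatch between matrices; markers: {bad_markers}, times: {bad_times}"
        )
    diff = a.mean_log2fc - b.mean_log2fc
    pos = diff.abs().to_numpy().argmax(axis=1)
    return pd.Series(
        diff.to_numpy()[np.arange(len(diff)), pos], index=diff.index, name="max_divergence"
    )
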