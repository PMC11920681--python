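"""Clean-up gating: the ordered cascade isolating single, live cells and
the target population (microglia or astrocytes).

The study's interactive polygon gates are replaced by declarative
one-dimensional thresholds and rectangular two-channel regions whose
bounds are estimated from the data (bimodal splits, quantile intervals),
making the cascade reproducible and auditable.  The standard microglia
cascade is:

1. debarcode quality — separation high, Mahalanobis low;
2. singlets — event length and center inside central quantile intervals
   (doublets fall outside the Gaussian-discrimination envelope);
3. viability — DNA intercalator above a bimodal split, length in range;
4. cerium removal — Ce140 below a split (residual calibration beads);
5. CD11b+/CD45+ double-positive region (microglia);
6. GFAP-negative (residual astrocyte removal).

All thresholds are estimated on arcsinh-transformed intensities
(cofactor 5); the raw intensity matrix is never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .debarcode import ConfigurationError
from .io import EventTable

__all__ = [
    "GateRule",
    "GateCascadeResult",
    "GateError",
    "arcsinh",
    "default_cascade",
    "estimate_thresholds",
    "apply_cascade",
]

COFACTOR = 5.0

PREDICATES = frozenset(
    {"threshold_above", "threshold_below", "interval", "quantile_interval", "two_channel_region"}
)


class GateError(RuntimeError):
    """Raised when a cascade cannot proceed (e.g. a gate removes everything)."""


def arcsinh(x, cofactor: float = COFACTOR) -> np.ndarray:
    """The standard variance-stabilizing transform for ion-count data."""
    return np.arcsinh(np.asarray(x, dtype=np.float64) / cofactor)


@dataclass(frozen=True)
class GateRule:
    """One pure filtering rule.

    ``inputs`` are 1–2 channel or annotation column names; ``predicate``
    one of ``threshold_above``, ``threshold_below``, ``interval``,
    ``quantile_interval``, ``two_channel_region``.  ``params`` holds the
    numeric bounds (on the arcsinh scale for intensity channels, raw for
    annotations); unset bounds (``None``) are filled by
    :func:`estimate_thresholds`.
    """

    name: str
    inputs: tuple
    predicate: str
    params: dict = field(default_factory=dict)
    on_annotations: bool = False

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(f"unknown predicate {self.predicate!r}")
        if not 1 <= len(self.inputs) <= 2:
            raise ValueError("a gate takes 1 or 2 inputs")


@dataclass
class GateCascadeResult:
    """Audit trail of one cascade application."""

    attrition: pd.DataFrame          # per gate: name, events_in, events_out, fraction
    final_index: np.ndarray          # surviving event indices (into the input table)
    rules: list[GateRule]
    composition: pd.DataFrame | None = None  # by ground-truth population, if available

    @property
    def n_retained(self) -> int:
        return len(self.final_index)


# ---------------------------------------------------------------------------
# cascade construction
# ---------------------------------------------------------------------------


def default_cascade(target: str = "microglia") -> list[GateRule]:
    """The ordered clean-up cascade for ``microglia``, ``astrocyte`` or
    ``all_cells`` (population gates omitted)."""
    common = [
        GateRule(
            "debarcode_quality", ("bc_separation", "bc_mahalanobis"), "two_channel_region",
            {"x_min": 0.3, "y_max": 30.0}, on_annotations=True,
        ),
        GateRule(
            "singlet", ("Event_length", "Center"), "quantile_interval",
            {"q_low": 0.01, "q_high": 0.99},
        ),
        GateRule(
            "viability", ("Ir191_DNA", "Event_length"), "two_channel_region",
            {"x_min": None, "y_max": None},
        ),
        GateRule("cerium_removal", ("Ce140",), "threshold_below", {"threshold": None}),
    ]
    if target == "all_cells":
        return common
    if target == "microglia":
        return common + [
            GateRule(
                "cd11b_cd45_double_positive", ("CD11b", "CD45"), "two_channel_region",
                {"x_min": None, "y_min": None},
            ),
            GateRule("gfap_negative", ("GFAP",), "threshold_below", {"threshold": None}),
        ]
    if target == "astrocyte":
        return common + [
            GateRule(
                "gfap_positive_cd11b_low", ("GFAP", "CD11b"), "two_channel_region",
                {"x_min": None, "y_max": None},
            ),
        ]
    raise ConfigurationError(f"unknown gating target {target!r}")


# ---------------------------------------------------------------------------
# threshold estimation
# ---------------------------------------------------------------------------


def _bimodal_split(x: np.ndarray, fallback_quantile: float) -> float:
    """Threshold between the two modes of a bimodal channel (2-means on
    the arcsinh scale); falls back to a quantile when the channel looks
    unimodal or constant."""
    x = np.asarray(x, dtype=np.float64)
    if np.ptp(x) == 0:
        warnings.warn("constant channel; falling back to quantile threshold", stacklevel=3)
        return float(x[0])
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(x.reshape(-1, 1))
    c = np.sort(km.cluster_centers_.ravel())
    labels = km.labels_
    spread = max(x[labels == 0].std(), x[labels == 1].std(), 1e-12)
    # modes must be well separated relative to their widths and by an
    # absolute margin, else a skewed unimodal channel gets falsely split
    if (c[1] - c[0]) < max(2.5 * spread, 0.5):
        warnings.warn(
            "channel looks unimodal; falling back to quantile threshold", stacklevel=3
        )
        return float(np.quantile(x, fallback_quantile))
    return float(0.5 * (c[0] + c[1]))


def estimate_thresholds(table: EventTable, rule: GateRule) -> GateRule:
    """Fill the unset bounds of ``rule`` from the data.

    Bimodal splits parameterize viability/cerium/marker gates; central
    quantile intervals (1–99% by default) parameterize the event-shape
    gates.  Requires >= 500 events for stable estimates.
    """
    if table.n_events < 500:
        raise ValueError(f"threshold estimation needs >= 500 events, got {table.n_events}")
    params = dict(rule.params)
    if rule.on_annotations:
        return rule

    def column(name: str) -> np.ndarray:
        return arcsinh(table.data(name))

    if rule.predicate == "quantile_interval":
        ql, qh = params.get("q_low", 0.01), params.get("q_high", 0.99)
        for ax, name in zip(("x", "y"), rule.inputs):
            x = column(name)
            params[f"{ax}_min"] = float(np.quantile(x, ql))
            params[f"{ax}_max"] = float(np.quantile(x, qh))
    elif rule.predicate in ("threshold_above", "threshold_below"):
        if params.get("threshold") is None:
            # unimodal fallback: a positivity gate keeps (almost) everything
            # rather than cutting into the single mode, and vice versa
            fallback = 0.02 if rule.predicate == "threshold_above" else 0.99
            params["threshold"] = _bimodal_split(column(rule.inputs[0]), fallback)
    elif rule.predicate == "two_channel_region":
        x = column(rule.inputs[0])
        if "x_min" in params and params["x_min"] is None:
            params["x_min"] = _bimodal_split(x, 0.02)
        if "x_max" in params and params["x_max"] is None:
            params["x_max"] = _bimodal_split(x, 0.99)
        if len(rule.inputs) == 2:
            y = column(rule.inputs[1])
            if "y_min" in params and params["y_min"] is None:
                params["y_min"] = _bimodal_split(y, 0.02)
            if "y_max" in params and params["y_max"] is None:
                if rule.name == "viability":
                    # upper length bound: central quantile, not a bimodal split
                    params["y_max"] = float(np.quantile(y, 0.995))
                else:
                    params["y_max"] = _bimodal_split(y, 0.99)
    elif rule.predicate == "interval":
        pass  # explicit bounds only
    return replace(rule, params=params)


# ---------------------------------------------------------------------------
# cascade application
# ---------------------------------------------------------------------------


def _evaluate(table: EventTable, rule: GateRule) -> np.ndarray:
    """Boolean pass mask for one parameterized rule over the whole table."""

    def column(name: str) -> np.ndarray:
        if rule.on_annotations:
            if name not in table.annotations.columns:
                raise ConfigurationError(f"gate {rule.name!r} needs annotation {name!r}")
            return table.annotations[name].to_numpy(dtype=np.float64)
        return arcsinh(table.data(name))

    p = rule.params
    if rule.predicate == "threshold_above":
        return column(rule.inputs[0]) > p["threshold"]
    if rule.predicate == "threshold_below":
        return column(rule.inputs[0]) < p["threshold"]
    if rule.predicate in ("interval", "quantile_interval"):
        mask = np.ones(table.n_events, dtype=bool)
        for ax, name in zip(("x", "y"), rule.inputs):
            x = column(name)
            if p.get(f"{ax}_min") is not None:
                mask &= x >= p[f"{ax}_min"]
            if p.get(f"{ax}_max") is not None:
                mask &= x <= p[f"{ax}_max"]
        return mask
    if rule.predicate == "two_channel_region":
        mask = np.ones(table.n_events, dtype=bool)
        for ax, name in zip(("x", "y"), rule.inputs):
            x = column(name)
            if p.get(f"{ax}_min") is not None:
                mask &= x >= p[f"{ax}_min"]
            if p.get(f"{ax}_max") is not None:
                mask &= x <= p[f"{ax}_max"]
        return mask
    raise AssertionError(rule.predicate)


def apply_cascade(
    table: EventTable,
    rules: list[GateRule],
    truth: pd.DataFrame | None = None,
    estimate: bool = True,
) -> GateCascadeResult:
    """Apply the rules in order, recording per-gate attrition.

    Unparameterized bounds are estimated on the events *surviving the
    preceding gates* (each gate sees the cleaned-up view, as interactive
    gating would).  If ``truth`` (a ground-truth frame with a
    ``population`` column) is supplied, the result carries a composition
    table of the final event set.

    Raises
    ------
    GateError
        If a gate removes 100% of the surviving events; the message names
        the gate.
    """
    surviving = np.arange(table.n_events)
    records = []
    fitted_rules: list[GateRule] = []
    for rule in rules:
        view = table.subset(surviving)
        if estimate and not rule.on_annotations:
            needs_fit = any(v is None for v in rule.params.values()) or (
                rule.predicate == "quantile_interval"
            )
            if needs_fit:
                rule = estimate_thresholds(view, rule)
        fitted_rules.append(rule)
        mask = _evaluate(view, rule)
        events_in = len(surviving)
        surviving = surviving[mask]
        records.append(
            {
                "gate": rule.name,
                "events_in": events_in,
                "events_out": len(surviving),
                "fraction_retained": len(surviving) / events_in if events_in else 0.0,
            }
        )
        if events_in and len(surviving) == 0:
            raise GateError(
                f"gate {rule.name!r} removed all {events_in} surviving events; "
                "cascade halted"
            )
    attrition = pd.DataFrame(records)
    composition = None
    if truth is not None and "population" in truth.columns:
        composition = (
            truth.iloc[surviving]["population"].value_counts(normalize=True)
            .rename("fraction").rename_axis("population").reset_index()
        )
    return GateCascadeResult(
        attrition=attrition, final_index=surviving, rules=fitted_rules,
        composition=composition,
    )
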