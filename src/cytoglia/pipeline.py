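"""End-to-end convenience drivers.

A pooled acquisition is processed in the fixed order the study's own
workflow follows: bead normalization (then bead removal), palladium
debarcoding with quality statistics, sample-metadata annotation, and the
clean-up gate cascade.  A full time course at three replicates exceeds
the 20 codes of a 6-choose-3 key, so the study design is simulated and
processed as one pooled run per replicate and the gated events are
concatenated for the bulk statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .debarcode import assign_barcodes, filter_assignments
from .gate import GateCascadeResult, apply_cascade, default_cascade
from .io import EventTable
from .normalize import BeadModel, normalize_run
from .synthetic import SimulationConfig, simulate_run, timecourse_config

__all__ = ["RunReport", "process_run", "simulate_and_process", "run_study"]


@dataclass
class RunReport:
    """Audit trail of one processed pool."""

    bead_model: BeadModel
    debarcode_attrition: pd.DataFrame
    cascade: GateCascadeResult
    n_input: int = 0
    n_output: int = 0
    extras: dict = field(default_factory=dict)


def process_run(
    table: EventTable,
    key,
    truth: pd.DataFrame | None = None,
    window_size: int = 500,
    target: str = "microglia",
    min_separation: float = 0.3,
    max_mahalanobis: float = 30.0,
) -> tuple[EventTable, RunReport, pd.DataFrame | None]:
    """Normalize, debarcode, annotate and gate one pooled run.

    Returns the gated :class:`EventTable` (annotated with the barcode
    quality statistics and, when the key carries metadata, the sample
    design columns), the :class:`RunReport`, and the ground-truth frame
    subset to the surviving events (or ``None``).
    """
    n_input = table.n_events
    corrected, model, kept = normalize_run(table, window_size=window_size)
    if truth is not None:
        truth = truth.loc[kept].reset_index(drop=True)

    assignments = assign_barcodes(corrected, key)
    retained, attrition = filter_assignments(
        assignments, min_separation=min_separation, max_mahalanobis=max_mahalanobis
    )
    annotated = EventTable(
        corrected.values, list(corrected.channels), assignments, list(corrected.provenance)
    )
    if key.metadata is not None:
        meta = key.metadata.reindex(assignments["bc_sample"])
        for c in meta.columns:
            annotated.annotations[c] = meta[c].to_numpy()

    cascade = apply_cascade(annotated, default_cascade(target), truth=truth)
    gated = annotated.subset(cascade.final_index)
    gated.log_stage(f"process_run:{target}")
    if truth is not None:
        truth = truth.iloc[cascade.final_index].reset_index(drop=True)
    report = RunReport(
        bead_model=model,
        debarcode_attrition=attrition,
        cascade=cascade,
        n_input=n_input,
        n_output=gated.n_events,
    )
    return gated, report, truth


def simulate_and_process(config: SimulationConfig, **process_kwargs):
    """Simulate one pooled run and push it through :func:`process_run`."""
    table, truth = simulate_run(config)
    return process_run(table, config.barcode_key, truth=truth, **process_kwargs)


def run_study(
    stimulus: str,
    composition: str,
    replicates=(1, 2, 3),
    events_per_sample: int = 2000,
    seed: int = 0,
    target: str = "microglia",
    **config_kwargs,
) -> tuple[EventTable, list[RunReport], pd.DataFrame]:
    """Simulate and process a full time course, one pooled run per replicate.

    Per-replicate seeds are derived deterministically from ``seed``.
    Returns the concatenated gated events (annotations carry stimulus,
    composition, time_h, replicate), the per-run reports, and the
    concatenated surviving ground truth.
    """
    gated_parts, reports, truth_parts = [], [], []
    for rep in replicates:
        cfg = timecourse_config(
            stimulus,
            composition,
            replicates=(rep,),
            events_per_sample=events_per_sample,
            seed=int(seed) * 1000 + int(rep),
            **config_kwargs,
        )
        gated, report, truth = simulate_and_process(cfg, target=target)
        gated_parts.append(gated)
        reports.append(report)
        truth_parts.append(truth)
    values = np.concatenate([g.values for g in gated_parts], axis=0)
    annotations = pd.concat([g.annotations for g in gated_parts], ignore_index=True)
    combined = EventTable(values, list(gated_parts[0].channels), annotations)
    combined.log_stage(f"run_study:{stimulus}:{composition}:{len(replicates)}replicates")
    truth_all = pd.concat(truth_parts, ignore_index=True)
    return combined, reports, truth_all
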