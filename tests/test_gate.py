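import warnings

import numpy as np
import pytest

from cytoglia import (
    ChannelInfo,
    EventTable,
    GateRule,
    apply_cascade,
    assign_barcodes,
    default_cascade,
    estimate_thresholds,
)
from cytoglia.debarcode import ConfigurationError, filter_assignments
from cytoglia.gate import GateError, arcsinh
from cytoglia.normalize import normalize_run


def test_default_cascades_shape():
    micro = default_cascade("microglia")
    assert [r.name for r in micro] == [
        "debarcode_quality", "singlet", "viability", "cerium_removal",
        "cd11b_cd45_double_positive", "gfap_negative",
    ]
    allc = default_cascade("all_cells")
    assert [r.name for r in allc] == [r.name for r in micro[:4]]
    astro = default_cascade("astrocyte")
    final = astro[-1]
    assert final.inputs[0] == "GFAP" and "x_min" in final.params
    with pytest.raises(ConfigurationError):
        default_cascade("neurons")


def test_empty_rule_list_is_identity(tiny_table):
    res = apply_cascade(tiny_table, [])
    assert res.n_retained == tiny_table.n_events
    assert len(res.attrition) == 0


def _bimodal_channel(rng, n, lo, hi, frac_hi):
    x = np.where(rng.random(n) < frac_hi, hi, lo)
    return x * rng.lognormal(0, 0.2, n)


def test_estimate_thresholds_bimodal_and_degenerate():
    rng = np.random.default_rng(1)
    n = 2000
    x = _bimodal_channel(rng, n, 1.0, 100.0, 0.5)
    table = EventTable(
        np.column_stack([x, np.ones(n)]),
        [ChannelInfo("GFAP", role="identity"), ChannelInfo("flat", role="other")],
    )
    rule = estimate_thresholds(
        table, GateRule("g", ("GFAP",), "threshold_below", {"threshold": None})
    )
    thr = rule.params["threshold"]
    assert arcsinh(1.5) < thr < arcsinh(80.0)  # strictly between the modes

    with pytest.warns(UserWarning, match="constant|unimodal"):
        fb = estimate_thresholds(
            table, GateRule("f", ("flat",), "threshold_below", {"threshold": None})
        )
    assert fb.params["threshold"] is not None

    with pytest.raises(ValueError, match="500"):
        estimate_thresholds(table.subset(np.arange(10)), rule)


def test_viability_threshold_recovers_live_cells(artifact_run):
    """The intercalator split keeps >= 99% of live cells and removes dead
    cells (planted with ~12x lower intercalator)."""
    _, table, truth = artifact_run
    rule = estimate_thresholds(
        table, GateRule("v", ("Ir191_DNA",), "threshold_above", {"threshold": None})
    )
    passed = arcsinh(table.data("Ir191_DNA")) > rule.params["threshold"]
    live = (~truth["is_dead"] & ~truth["is_bead"]).to_numpy()
    dead = (truth["is_dead"] & ~truth["is_doublet"]).to_numpy()
    assert passed[live].mean() >= 0.99
    assert passed[dead].mean() <= 0.05


def test_cascade_purity_recall_and_monotonicity(artifact_run):
    """On the artifact-spiked run the microglia cascade reaches purity
    >= 0.95 and recall >= 0.9 against ground truth, with monotone
    attrition."""
    cfg, table, truth = artifact_run
    corrected, model, kept = normalize_run(table, window_size=200)
    truth_k = truth.loc[kept].reset_index(drop=True)
    asg = assign_barcodes(corrected, cfg.barcode_key)
    annotated = EventTable(corrected.values, list(corrected.channels), asg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = apply_cascade(annotated, default_cascade("microglia"), truth=truth_k)

    assert (res.attrition["events_out"] <= res.attrition["events_in"]).all()
    assert (res.attrition["events_in"].iloc[1:].to_numpy()
            == res.attrition["events_out"].iloc[:-1].to_numpy()).all()

    fin = truth_k.iloc[res.final_index]
    is_good = (
        (fin["population"] == "microglia")
        & ~fin["is_doublet"] & ~fin["is_dead"] & ~fin["is_bead"]
    )
    all_good = (
        (truth_k["population"] == "microglia")
        & ~truth_k["is_doublet"] & ~truth_k["is_dead"] & ~truth_k["is_bead"]
    )
    assert is_good.mean() >= 0.95
    assert is_good.sum() / all_good.sum() >= 0.9
    assert res.composition is not None
    top = res.composition.sort_values("fraction", ascending=False).iloc[0]
    assert top["population"] == "microglia"


def test_threshold_gate_order_does_not_change_final_set(tiny_table):
    """Pure marginal thresholds commute: the final retained set is the
    intersection regardless of application order."""
    rules = [
        GateRule("a", ("CD11b",), "threshold_above", {"threshold": 0.1}),
        GateRule("b", ("pERK",), "threshold_below", {"threshold": 1.0}),
    ]
    fwd = apply_cascade(tiny_table, rules, estimate=False)
    rev = apply_cascade(tiny_table, rules[::-1], estimate=False)
    np.testing.assert_array_equal(np.sort(fwd.final_index), np.sort(rev.final_index))


def test_gate_removing_everything_raises(tiny_table):
    rule = GateRule("impossible", ("pERK",), "threshold_above", {"threshold": 1e9})
    with pytest.raises(GateError, match="impossible"):
        apply_cascade(tiny_table, [rule], estimate=False)


def test_cascade_determinism(artifact_run):
    _, table, _ = artifact_run
    sub = table.subset(np.arange(4000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = apply_cascade(sub, default_cascade("all_cells")[1:])
        r2 = apply_cascade(sub, default_cascade("all_cells")[1:])
    np.testing.assert_array_equal(r1.final_index, r2.final_index)
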