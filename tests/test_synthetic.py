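import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytoglia import (
    MarkerDynamics,
    default_dynamics,
    response_mean,
    simulate_run,
    simulate_signaling_states,
    timecourse_config,
)
from cytoglia.debarcode import ConfigurationError
from cytoglia.synthetic import DEFAULT_TIME_POINTS, archetype_weights


def test_response_mean_anchor_points():
    d = MarkerDynamics("pERK", baseline=15.0, peak_fold=16.8, peak_time=0.25,
                       onset_time=0.05, decay_time=1.0, persistent_fraction=0.0)
    assert response_mean(d, 0.0) == pytest.approx(15.0)
    assert response_mean(d, 0.25) == pytest.approx(15.0 * 16.8)
    assert response_mean(d, 1000.0) == pytest.approx(15.0, rel=1e-6)


def test_response_mean_persistent_plateau():
    d = MarkerDynamics("CD40", baseline=8.0, peak_fold=9.0, peak_time=24.0,
                       onset_time=2.0, decay_time=4.0, persistent_fraction=0.5)
    plateau = 8.0 * (1 + 0.5 * 8.0)
    assert response_mean(d, 1e6) == pytest.approx(plateau, rel=1e-6)


@settings(max_examples=50, deadline=None)
@given(
    t1=st.floats(0.06, 0.24),
    t2=st.floats(0.06, 0.24),
)
def test_response_mean_monotone_rise(t1, t2):
    """Between onset and peak the response is monotone in time."""
    d = MarkerDynamics("pS6", baseline=8.0, peak_fold=25.0, peak_time=0.25,
                       onset_time=0.05, decay_time=2.0)
    lo, hi = sorted((t1, t2))
    assert response_mean(d, lo) <= response_mean(d, hi) + 1e-12


def test_declining_marker_falls_below_baseline():
    d = default_dynamics("LPS")["Cx3CR1"]
    assert d.peak_fold < 1.0
    assert response_mean(d, 24.0) < d.baseline


def test_default_dynamics_planted_amplitudes():
    lps = default_dynamics("LPS", "microglia_only")
    pic = default_dynamics("PIC", "microglia_only")
    assert lps["pERK"].peak_fold == pytest.approx(16.8)
    assert pic["pERK"].peak_fold == pytest.approx(3.8)
    assert pic["pERK"].peak_time > lps["pERK"].peak_time  # delayed kinetics
    assert lps["pS6"].peak_fold == pytest.approx(25.0)
    assert lps["pS6"].peak_time == pytest.approx(1.0)
    assert lps["CD40"].peak_fold == pytest.approx(9.0)
    assert pic["CD40"].peak_fold == pytest.approx(20.0)
    for stim in ("LPS", "PIC"):
        mixed = default_dynamics(stim, "mixed")
        assert mixed["CD40"].peak_fold <= 2.0
    with pytest.raises(ConfigurationError):
        default_dynamics("TNF")


def test_simulate_run_deterministic_under_seed():
    cfg = timecourse_config("LPS", "microglia_only", events_per_sample=200, seed=3)
    t1, truth1 = simulate_run(cfg)
    t2, truth2 = simulate_run(cfg)
    np.testing.assert_array_equal(t1.values, t2.values)
    pd.testing.assert_frame_equal(truth1, truth2)


def test_noiseless_run_recovers_dynamics_means():
    """With cv -> 0 and artifacts off, per-sample marker means equal the
    dynamics-implied means within 1%."""
    cfg = timecourse_config(
        "LPS", "microglia_only",
        events_per_sample=5000, seed=4,
        cv=0.0, doublet_rate=0.0, dead_rate=0.0, bead_fraction=0.0, drift_final=1.0,
    )
    table, truth = simulate_run(cfg)
    dyn = default_dynamics("LPS", "microglia_only")
    for t_h in (0.0, 0.25, 1.0, 24.0):
        sample_mask = (truth["time_h"] == t_h) & (truth["population"] == "microglia")
        for marker in ("pERK", "pS6", "CD40"):
            expected = response_mean(dyn[marker], t_h)
            observed = table.data(marker)[sample_mask.to_numpy()].mean()
            assert observed == pytest.approx(expected, rel=0.01)


def test_bead_count_binomial():
    """bead_fraction 1/21 over 21,000 cells plants ~1,000 beads (3-sigma)."""
    cfg = timecourse_config(
        "LPS", "microglia_only", replicates=(1,),
        events_per_sample=2100, seed=8, doublet_rate=0.0, dead_rate=0.0,
    )
    _, truth = simulate_run(cfg)
    n_cells = (~truth["is_bead"]).sum()
    assert n_cells == 21000
    n, p = 21000, 1 / 21
    sigma = np.sqrt(n * p * (1 - p))
    assert abs(truth["is_bead"].sum() - n * p) <= 3 * sigma


def test_ground_truth_flags_partition(artifact_run):
    _, table, truth = artifact_run
    assert len(truth) == table.n_events
    assert not (truth["is_bead"] & truth["is_doublet"]).any()
    assert not (truth["is_bead"] & truth["is_dead"]).any()
    assert truth.loc[truth["is_bead"], "sample"].isna().all()
    assert truth.loc[~truth["is_bead"], "sample"].notna().all()
    # acquisition order is a permutation
    assert (np.sort(truth["acquisition_index"].to_numpy()) == np.arange(len(truth))).all()


def test_exact_event_counts_before_artifacts():
    cfg = timecourse_config(
        "PIC", "mixed", events_per_sample=300, seed=5,
        doublet_rate=0.0, dead_rate=0.0, bead_fraction=0.0,
    )
    _, truth = simulate_run(cfg)
    assert (truth.groupby("sample").size() == 300).all()


def test_archetype_weights_are_a_distribution():
    for stim in ("LPS", "PIC"):
        for comp in ("microglia_only", "mixed"):
            for t in DEFAULT_TIME_POINTS:
                w = archetype_weights(stim, comp, t)
                assert all(v >= 0 for v in w.values())
                assert sum(w.values()) == pytest.approx(1.0)
    # prevalence anchors: MAPK 73% at 15 min (LPS); late-state divergence at 48 h
    assert archetype_weights("LPS", "microglia_only", 0.25)["mapk"] == pytest.approx(0.73)
    assert archetype_weights("PIC", "mixed", 48.0)["cd40"] == pytest.approx(0.0368)


def test_signaling_state_simulation_deterministic():
    t1, tr1 = simulate_signaling_states("LPS", n_per_sample=50, seed=2)
    t2, tr2 = simulate_signaling_states("LPS", n_per_sample=50, seed=2)
    np.testing.assert_array_equal(t1.values, t2.values)
    assert (tr1["archetype"] == tr2["archetype"]).all()
    assert t1.n_events == 50 * 10 * 3
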