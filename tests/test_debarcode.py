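import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from cytoglia import (
    BarcodeKey,
    assign_barcodes,
    filter_assignments,
    rescale_barcode_channels,
    simulate_run,
    timecourse_config,
)
from cytoglia.debarcode import ConfigurationError
from cytoglia.panel import BARCODE_CHANNELS

from conftest import barcode_table


def test_key_validation():
    key = BarcodeKey.full()
    assert len(key.codes) == 20
    with pytest.raises(ConfigurationError, match="3-subset"):
        BarcodeKey({"a": frozenset(BARCODE_CHANNELS[:2])})
    with pytest.raises(ConfigurationError, match="share"):
        BarcodeKey(
            {"a": frozenset(BARCODE_CHANNELS[:3]), "b": frozenset(BARCODE_CHANNELS[:3])}
        )


def test_rescale_symmetric_and_degenerate_events():
    table, i = barcode_table([[10, 10, 10, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
    r = rescale_barcode_channels(table)
    np.testing.assert_allclose(r[i], [1, 1, 1, 0, 0, 0])
    np.testing.assert_allclose(r[i + 1], np.zeros(6))


def test_rescale_invariant_to_per_channel_scaling():
    """Multiplying any barcode channel by a positive constant (a staining
    intensity change) cancels against that channel's robust span, so the
    rescaled matrix — and hence every event's channel ranking — is
    unchanged."""
    rng = np.random.default_rng(7)
    raw = rng.gamma(2.0, 30.0, size=(300, 6))
    table, i = barcode_table(raw, n_background=0)
    r1 = rescale_barcode_channels(table)
    gains = rng.uniform(0.2, 8.0, size=6)
    table2, _ = barcode_table(raw * gains, n_background=0)
    r2 = rescale_barcode_channels(table2)
    np.testing.assert_allclose(r1, r2, rtol=1e-5, atol=1e-7)


def test_rescale_rejects_dead_channel():
    table, _ = barcode_table([[1, 1, 1, 0, 0, 0]], background=0.0, n_background=5)
    values = table.values.copy()
    values[:, 5] = 0.0
    table2 = type(table)(values, table.channels)
    with pytest.raises(ConfigurationError, match="identically zero"):
        rescale_barcode_channels(table2)


def test_assignment_separation_and_bc_neg_arithmetic():
    """Clean singlet: separation 1, bc_neg 0.  Graded event: separation =
    3rd - 4th rescaled value.  Raw (120, 95, 88, 6, 3, 1) under code
    {ch1,ch2,ch3}: bc_neg = 10."""
    rows = [
        [50, 50, 50, 0, 0, 0],
        [1.0, 0.9, 0.7, 0.2, 0.1, 0.0],
        [120, 95, 88, 6, 3, 1],
    ]
    table, i = barcode_table(rows)
    key = BarcodeKey({"s1": frozenset(BARCODE_CHANNELS[:3])})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few events per sample -> Mahalanobis warning
        asg = assign_barcodes(table, key)
    assert asg.loc[i, "bc_sample"] == "s1"
    assert asg.loc[i, "bc_separation"] == pytest.approx(1.0)
    assert asg.loc[i, "bc_neg"] == pytest.approx(0.0)
    assert asg.loc[i + 1, "bc_separation"] == pytest.approx(0.5, abs=1e-6)
    assert asg.loc[i + 2, "bc_neg"] == pytest.approx(10.0)


def test_candidate_outside_key_is_unassigned():
    table, i = barcode_table([[0, 0, 0, 9, 9, 9]])
    key = BarcodeKey({"s1": frozenset(BARCODE_CHANNELS[:3])})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        asg = assign_barcodes(table, key)
    assert pd.isna(asg.loc[i, "bc_sample"])
    assert asg.loc[i, "bc_separation"] > 0  # separation retained when unassigned


def test_permutation_equivariance():
    """Relabeling barcode channels together with the key leaves sample
    assignments unchanged."""
    cfg = timecourse_config("LPS", "microglia_only", events_per_sample=150, seed=13,
                            bead_fraction=0.0, doublet_rate=0.0, dead_rate=0.0,
                            drift_final=1.0)
    table, _ = simulate_run(cfg)
    asg = assign_barcodes(table, cfg.barcode_key)

    perm = [3, 0, 5, 1, 4, 2]
    permuted_channels = tuple(np.array(cfg.barcode_key.channels)[perm])
    # move the data columns the same way: channel at new position j holds
    # what the original channel permuted_channels[j] held
    new_values = table.values.copy()
    for new_name, old_name in zip(cfg.barcode_key.channels, permuted_channels):
        new_values[:, table.channel_index(new_name)] = table.data(old_name)
    rename = dict(zip(permuted_channels, cfg.barcode_key.channels))
    new_codes = {
        s: frozenset(rename[c] for c in code) for s, code in cfg.barcode_key.codes.items()
    }
    table2 = type(table)(new_values, table.channels)
    key2 = BarcodeKey(new_codes, cfg.barcode_key.channels)
    asg2 = assign_barcodes(table2, key2)
    assert (asg["bc_sample"].fillna("-") == asg2["bc_sample"].fillna("-")).all()


def test_mahalanobis_small_near_center_nonnegative():
    rng = np.random.default_rng(3)
    raw = 100 + rng.normal(0, 5, size=(200, 6))
    raw[:, 3:] = rng.exponential(0.5, size=(200, 3))
    raw = np.vstack([raw, raw.mean(axis=0)])
    table, i = barcode_table(raw, n_background=0)
    key = BarcodeKey({"s1": frozenset(BARCODE_CHANNELS[:3])})
    asg = assign_barcodes(table, key)
    assert (asg["bc_mahalanobis"] >= 0).all()
    center = asg["bc_mahalanobis"].iloc[-1]
    assert center < asg["bc_mahalanobis"].iloc[i:-1].mean()


def test_vacuous_filter_keeps_all_assigned(artifact_run):
    cfg, table, _ = artifact_run
    asg = assign_barcodes(table, cfg.barcode_key)
    retained, attrition = filter_assignments(
        asg, min_separation=0.0, max_mahalanobis=np.inf, max_bc_neg=None
    )
    assert len(retained) == asg["bc_sample"].notna().sum()
    assert attrition["removed"].iloc[1:].sum() == 0


def test_retained_events_carry_true_sample(artifact_run):
    """>= 99% of confidently retained events map back to their true sample."""
    cfg, table, truth = artifact_run
    asg = assign_barcodes(table, cfg.barcode_key)
    retained, _ = filter_assignments(asg)
    match = asg.loc[retained, "bc_sample"].to_numpy() == truth.loc[retained, "sample"].to_numpy()
    assert match.mean() >= 0.99


def test_barcode_doublets_have_higher_bc_neg(artifact_run):
    """Cross-sample doublets pool two codes, so their bc_neg exceeds the
    singlets' (one-sided rank-sum), and a per-sample 95th-percentile cut
    removes >= 80% of the assigned doublets."""
    cfg, table, truth = artifact_run
    asg = assign_barcodes(table, cfg.barcode_key)
    assigned = asg["bc_sample"].notna().to_numpy()
    cross = (
        truth["is_doublet"]
        & truth["doublet_partner"].notna()
        & (truth["doublet_partner"] != truth["sample"])
    ).to_numpy()
    singlet = (~truth["is_doublet"] & ~truth["is_bead"]).to_numpy()
    db = asg.loc[assigned & cross, "bc_neg"].dropna()
    sg = asg.loc[assigned & singlet, "bc_neg"].dropna()
    assert mannwhitneyu(db, sg, alternative="greater").pvalue < 1e-6

    retained, _ = filter_assignments(
        asg, min_separation=0.0, max_mahalanobis=np.inf, max_bc_neg="p95"
    )
    kept = np.zeros(len(asg), bool)
    kept[retained] = True
    removed_doublets = 1 - kept[assigned & cross].mean()
    assert removed_doublets >= 0.8


def test_zero_off_code_intensity_gives_exact_zero_bc_neg():
    table, i = barcode_table([[33, 44, 55, 0, 0, 0]])
    key = BarcodeKey({"s1": frozenset(BARCODE_CHANNELS[:3])})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        asg = assign_barcodes(table, key)
    assert asg.loc[i, "bc_neg"] == 0.0
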