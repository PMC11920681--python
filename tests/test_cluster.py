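import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cytoglia import (
    ChannelInfo,
    EventTable,
    abundance_trajectories,
    cluster_fraction,
    embed_umap,
    leiden_partition,
    preprocess_for_clustering,
    rmse_baseline_return,
    round1_identity_clustering,
    simulate_run,
    simulate_signaling_states,
    timecourse_config,
    two_round_clustering,
    zscore_annotate,
)
from cytoglia.cluster import AbundanceTrajectory


def test_preprocess_arcsinh_and_monotonicity():
    vals = np.array([[0.0], [5.0], [50.0], [500.0]], dtype=np.float32)
    table = EventTable(vals, [ChannelInfo("pERK", role="signaling")])
    feats = preprocess_for_clustering(table, ["pERK"])
    assert feats[0, 0] == 0.0
    # arcsinh(5/5) = arcsinh(1) ~ 0.8814 before percentile scaling
    scale = np.percentile(np.arcsinh(vals[:, 0] / 5.0), 99.5)
    assert feats[1, 0] == pytest.approx(np.arcsinh(1.0) / scale, rel=1e-6)
    assert (np.diff(feats[:, 0]) > 0).all()


def test_preprocess_constant_marker_zero_scaled():
    vals = np.zeros((10, 1), dtype=np.float32)
    table = EventTable(vals, [ChannelInfo("flat", role="signaling")])
    with pytest.warns(UserWarning, match="constant"):
        feats = preprocess_for_clustering(table, ["flat"])
    assert (feats == 0).all()


def _blobs(rng, n=1000, sep=10.0):
    a = rng.normal(0, 1, size=(n, 5))
    b = rng.normal(sep, 1, size=(n, 5))
    return np.vstack([a, b]), np.repeat([0, 1], n)


def test_leiden_two_blobs_and_determinism():
    rng = np.random.default_rng(0)
    X, truth = _blobs(rng)
    labels = leiden_partition(X, resolution=0.05, seed=4)
    assert labels.max() == 2
    assert adjusted_rand_score(truth, labels) >= 0.99
    labels2 = leiden_partition(X, resolution=0.05, seed=4)
    np.testing.assert_array_equal(labels, labels2)
    with pytest.raises(ValueError, match="neighbors"):
        leiden_partition(X[:10], neighbors=15)


def test_round1_excludes_contaminants_in_mixed_culture():
    """Astrocyte- and fibronectin-high-dominated identity clusters are
    excluded; the retained events are >= 90% true microglia."""
    cfg = timecourse_config(
        "LPS", "mixed", replicates=(1,), time_points=(0.0,),
        events_per_sample=4000, seed=19,
        bead_fraction=0.0, doublet_rate=0.0, dead_rate=0.0, drift_final=1.0,
    )
    table, truth = simulate_run(cfg)
    labels, excluded = round1_identity_clustering(table, seed=3)
    assert excluded
    retained = ~np.isin(labels, excluded)
    assert (truth.loc[retained, "population"] == "microglia").mean() >= 0.9


def test_round1_pure_culture_excludes_nothing():
    table, _ = simulate_signaling_states("LPS", n_per_sample=100, replicates=1, seed=23)
    _, excluded = round1_identity_clustering(table, seed=3)
    assert excluded == []


def test_two_round_recovers_archetypes():
    """The 4-archetype simulation is recovered with ARI >= 0.8; excluded
    events carry no round-2 label."""
    table, truth = simulate_signaling_states("LPS", n_per_sample=120, seed=29)
    model = two_round_clustering(table, target_band=(3, 6), seed=5)
    r2 = model.round2_labels
    assert np.isnan(r2[np.isin(model.round1_labels, model.excluded_clusters)]).all()
    sub = model.retained_index
    ari = adjusted_rand_score(truth["archetype"].iloc[sub], r2[sub].astype(int))
    assert ari >= 0.8
    # z-score hi/lo labels flag the planted archetype markers
    ann = model.annotations
    assert any((ann["pERK"] == "hi") & (ann["pp38"] == "hi"))
    assert any(ann["pSTAT1"] == "hi")
    assert any((ann["CD40"] == "hi") & (ann["CD86"] == "hi"))


def test_zscore_hand_computed_vector():
    """Cluster means (0, 0, 0, 10) give z = (-1, -1, -1, 3)/sqrt(3) under
    the population-SD convention: the high cluster reaches z = sqrt(3)
    and is labeled 'hi', and z-scores center to 0."""
    values = np.concatenate([np.zeros(30), np.full(10, 10.0)]).reshape(-1, 1)
    table = EventTable(values.astype(np.float32), [ChannelInfo("CD40", role="identity")])
    labels = np.concatenate([np.repeat([1, 2, 3], 10), np.full(10, 4)])
    z, ann = zscore_annotate(table, labels, markers=["CD40"])
    s3 = np.sqrt(3.0)
    np.testing.assert_allclose(z["CD40"], [-1 / s3, -1 / s3, -1 / s3, s3], atol=1e-9)
    assert list(ann["CD40"]) == ["", "", "", "hi"]
    assert z["CD40"].sum() == pytest.approx(0.0, abs=1e-12)


def test_zscore_flat_marker_and_single_cluster():
    values = np.ones((20, 1), dtype=np.float32)
    table = EventTable(values, [ChannelInfo("m", role="signaling")])
    labels = np.repeat([1, 2], 10)
    z, ann = zscore_annotate(table, labels, markers=["m"])
    assert (z["m"] == 0).all() and (ann["m"] == "").all()
    with pytest.raises(ValueError, match="2 clusters"):
        zscore_annotate(table, np.ones(20), markers=["m"])


def _meta(times, reps=(1,), cond="LPS", n=1):
    rows = []
    for r in reps:
        for t in times:
            for _ in range(n):
                rows.append({"stimulus": cond, "time_h": t, "replicate": r})
    return pd.DataFrame(rows)


def test_abundance_single_cluster_uniform():
    times = tuple(float(t) for t in range(10))
    meta = _meta(times, n=3)
    labels = np.ones(len(meta))
    traj = abundance_trajectories(labels, meta)
    assert (traj.fractions["LPS"].loc[1] == 1.0).all()
    np.testing.assert_allclose(traj.time_normalized["LPS"].loc[1], 0.1)


def test_abundance_ordering_and_normalization():
    """An early-pulse cluster gets an earlier rank than a late cluster, and
    fractions sum to 1 per time point."""
    meta = _meta((0.0, 1.0, 2.0), n=10)
    labels = np.where(meta["time_h"] < 1.0, 1, 2)  # cluster 1 early, 2 late
    labels[0] = 2  # keep both clusters present at t = 0
    traj = abundance_trajectories(labels, meta)
    assert traj.ordering[1] < traj.ordering[2]
    sums = traj.fractions["LPS"].sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_missing_time_point_absent_not_zero():
    meta = _meta((0.0, 2.0), n=5)
    labels = np.ones(len(meta))
    traj = abundance_trajectories(labels, meta)
    assert list(traj.fractions["LPS"].columns) == [0.0, 2.0]


def _manual_traj(vec0, vec48):
    mat = pd.DataFrame({0.0: vec0, 48.0: vec48})
    mat.index.name = "cluster"
    return AbundanceTrajectory(
        fractions={"LPS": mat}, replicate_fractions=pd.DataFrame(),
        time_normalized={}, ordering=pd.Series(dtype=int),
    )


def test_rmse_hand_values():
    traj = _manual_traj([0.4, 0.6], [0.4, 0.6])
    assert rmse_baseline_return(traj, "LPS") == 0.0
    traj2 = _manual_traj([0.50, 0.50], [0.53, 0.46])
    expected = np.sqrt((0.03**2 + 0.04**2) / 2)
    assert rmse_baseline_return(traj2, "LPS") == pytest.approx(expected, abs=1e-12)
    assert rmse_baseline_return(traj2, "LPS", scale="percent") == pytest.approx(
        100 * expected, abs=1e-10
    )
    # invariant to cluster relabeling
    traj3 = _manual_traj([0.50, 0.50], [0.46, 0.53])
    assert rmse_baseline_return(traj3, "LPS") == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError, match="missing"):
        rmse_baseline_return(traj2, "LPS", t_end=24.0)


def test_cluster_fraction_arithmetic():
    meta = _meta((0.0,), n=200)
    labels = np.where(np.arange(200) < 146, 5, 6)
    assert cluster_fraction(labels, meta, 5, condition="LPS", time_h=0.0) == pytest.approx(0.73)
    assert cluster_fraction(np.full(200, 5), meta, 5) == 1.0
    assert np.isnan(cluster_fraction(labels, meta, 5, condition="PIC"))


def test_umap_embedding_separates_blobs():
    rng = np.random.default_rng(2)
    X, truth = _blobs(rng, n=150, sep=12.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = embed_umap(X, seed=7)
    assert emb.shape == (300, 2)
    a, b = emb[truth == 0], emb[truth == 1]
    gap = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    r95 = max(
        np.percentile(np.linalg.norm(a - a.mean(axis=0), axis=1), 95),
        np.percentile(np.linalg.norm(b - b.mean(axis=0), axis=1), 95),
    )
    assert gap > r95
    with pytest.raises(ValueError, match="finite"):
        embed_umap(np.array([[np.nan, 1.0]] * 30))
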