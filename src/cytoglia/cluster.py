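"""Two-round community-detection workflow and temporal cluster analytics.

Round 1 partitions cells on identity markers and excludes clusters that
are not microglia (low CD11b and/or low CD45 and/or high GFAP, judged by
cluster medians against global quantiles).  Round 2 re-partitions the
retained microglia on all panel markers except the four identity anchors
(CD11b, CD45, GFAP, Olig2), resolving signaling states.  Clusters are
annotated by z-scoring each marker's cluster means across clusters
("hi" at z >= 1.5, "lo" at z <= -1.5), ordered along the time course by
their abundance-weighted mean time, and summarized by per-condition
abundance trajectories and the RMSE baseline-return metric (how far the
48 h cluster composition sits from the 0 h composition).

Partitioning is Leiden community detection on a k-nearest-neighbor graph
(Euclidean, k = 15 by default — the same neighborhood size as the UMAP
embedding); the arcsinh cofactor-5 transform with per-marker 99.5th
percentile scaling feeds both rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .debarcode import ConfigurationError
from .gate import arcsinh
from .io import EventTable
from .panel import IDENTITY_MARKERS, ROUND2_EXCLUDED

__all__ = [
    "ClusterModel",
    "AbundanceTrajectory",
    "preprocess_for_clustering",
    "leiden_partition",
    "round1_identity_clustering",
    "round2_signaling_clustering",
    "zscore_annotate",
    "abundance_trajectories",
    "rmse_baseline_return",
    "cluster_fraction",
    "embed_umap",
    "two_round_clustering",
]

HI_Z = 1.5
LO_Z = -1.5


@dataclass
class ClusterModel:
    """Result of the two-round workflow.

    ``round1_labels`` covers all input events; ``round2_labels`` is NaN
    for events whose round-1 cluster was excluded as non-microglia.
    """

    round1_labels: np.ndarray
    excluded_clusters: list[int]
    retained_index: np.ndarray
    round2_labels: np.ndarray  # float, NaN where excluded
    zscores: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    embedding: np.ndarray | None = None
    params: dict = field(default_factory=dict)


@dataclass
class AbundanceTrajectory:
    """Cluster x time x condition abundance tables.

    ``fractions``: per (condition, time) mean-over-replicate cluster
    fractions (rows: cluster, columns: time), one frame per condition;
    ``replicate_fractions``: the underlying per-replicate long table;
    ``time_normalized``: each cluster's series divided by its own sum over
    time (rows sum to 1); ``ordering``: cluster -> rank by
    abundance-weighted mean time index (early clusters first).
    """

    fractions: dict[str, pd.DataFrame]
    replicate_fractions: pd.DataFrame
    time_normalized: dict[str, pd.DataFrame]
    ordering: pd.Series


# ---------------------------------------------------------------------------
# features and partitioning
# ---------------------------------------------------------------------------


def preprocess_for_clustering(table: EventTable, markers: list[str]) -> np.ndarray:
    """Event x marker feature matrix: arcsinh (cofactor 5) then division
    by the per-marker 99.5th percentile of the transformed values.

    Constant markers are retained as all-zero columns (with a warning)
    so the feature order always matches ``markers``.
    """
    feats = np.empty((table.n_events, len(markers)), dtype=np.float64)
    for j, m in enumerate(markers):
        x = arcsinh(table.data(m))
        scale = np.percentile(x, 99.5)
        if scale <= 0:
            if np.ptp(x) == 0:
                warnings.warn(f"marker {m!r} is constant; zero-scaled", stacklevel=2)
            feats[:, j] = 0.0
        else:
            feats[:, j] = x / scale
    return feats


def leiden_partition(
    features: np.ndarray,
    neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition of the kNN graph (Euclidean, k = ``neighbors``).

    Labels are 1-based and ordered by descending cluster size.
    """
    n = len(features)
    if neighbors >= n:
        raise ValueError(f"neighbors ({neighbors}) must be < number of events ({n})")
    nn = NearestNeighbors(n_neighbors=neighbors + 1).fit(features)
    _, idx = nn.kneighbors(features)
    src = np.repeat(np.arange(n), neighbors)
    dst = idx[:, 1:].ravel()
    edges = np.stack([np.minimum(src, dst), np.maximum(src, dst)], axis=1)
    edges = np.unique(edges, axis=0)
    graph = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel 1..K by descending size (stable tie-break on original id)
    sizes = pd.Series(raw).value_counts().sort_values(ascending=False, kind="stable")
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    return np.array([remap[r] for r in raw])


# ---------------------------------------------------------------------------
# the two rounds
# ---------------------------------------------------------------------------


def round1_identity_clustering(
    table: EventTable,
    neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    low_quantile: float = 0.25,
    high_quantile: float = 0.75,
    identity_markers=IDENTITY_MARKERS,
) -> tuple[np.ndarray, list[int]]:
    """Identity-round partition plus the excluded (non-microglia) clusters.

    A cluster is excluded when its median CD11b or CD45 (arcsinh scale)
    falls below the ``low_quantile`` of the global per-marker distribution,
    or its median GFAP rises above the ``high_quantile`` — the automated
    form of the violin-plot judgment that drops astrocyte- and
    contaminant-dominated clusters.  Each quantile threshold is guarded by
    a minimum margin (0.5 arcsinh units) from the global median, so in a
    homogeneous culture — where the quantiles sit inside the single mode's
    noise — no cluster is excluded by chance.
    """
    markers = [m for m in identity_markers if m in table.channel_names]
    feats = preprocess_for_clustering(table, markers)
    labels = leiden_partition(feats, neighbors=neighbors, resolution=resolution, seed=seed)

    margin = 0.5
    cd11b = arcsinh(table.data("CD11b"))
    cd45 = arcsinh(table.data("CD45"))
    gfap = arcsinh(table.data("GFAP"))
    lo_cd11b = min(np.quantile(cd11b, low_quantile), np.median(cd11b) - margin)
    lo_cd45 = min(np.quantile(cd45, low_quantile), np.median(cd45) - margin)
    hi_gfap = max(np.quantile(gfap, high_quantile), np.median(gfap) + margin)

    excluded = []
    for c in np.unique(labels):
        members = labels == c
        if (
            np.median(cd11b[members]) < lo_cd11b
            or np.median(cd45[members]) < lo_cd45
            or np.median(gfap[members]) > hi_gfap
        ):
            excluded.append(int(c))
    if len(excluded) == len(np.unique(labels)):
        raise ConfigurationError("all identity clusters excluded; check exclusion quantiles")
    return labels, excluded


def round2_signaling_clustering(
    table: EventTable,
    neighbors: int = 15,
    seed: int = 0,
    target_band: tuple[int, int] = (15, 25),
    resolution_grid=None,
) -> tuple[np.ndarray, float]:
    """Signaling-round partition on all markers except the identity anchors.

    The Leiden resolution is searched over a geometric grid until the
    cluster count lands in ``target_band``; if the band is unreachable the
    resolution with the nearest count is used, with a warning.  Returns
    ``(labels, resolution)``.
    """
    markers = [m for m in table.marker_names() if m not in ROUND2_EXCLUDED]
    feats = preprocess_for_clustering(table, markers)
    if resolution_grid is None:
        resolution_grid = np.geomspace(0.01, 10.0, 17)
    lo, hi = target_band
    best_labels, best_res, best_dist = None, None, np.inf
    for res in resolution_grid:
        labels = leiden_partition(feats, neighbors=neighbors, resolution=float(res), seed=seed)
        k = labels.max()
        if lo <= k <= hi:
            return labels, float(res)
        dist = min(abs(k - lo), abs(k - hi))
        if dist < best_dist:
            best_labels, best_res, best_dist = labels, float(res), dist
    warnings.warn(
        f"no resolution in the grid yields {lo}-{hi} clusters; "
        f"using resolution {best_res:g} with {best_labels.max()} clusters",
        stacklevel=2,
    )
    return best_labels, best_res


def two_round_clustering(
    table: EventTable,
    neighbors: int = 15,
    seed: int = 0,
    round1_resolution: float = 1.0,
    target_band: tuple[int, int] = (15, 25),
) -> ClusterModel:
    """Run both rounds and return the assembled :class:`ClusterModel`."""
    r1, excluded = round1_identity_clustering(
        table, neighbors=neighbors, resolution=round1_resolution, seed=seed
    )
    retained = np.flatnonzero(~np.isin(r1, excluded))
    sub = table.subset(retained)
    r2_sub, res = round2_signaling_clustering(
        sub, neighbors=neighbors, seed=seed, target_band=target_band
    )
    r2 = np.full(table.n_events, np.nan)
    r2[retained] = r2_sub
    markers = [m for m in table.marker_names() if m not in ROUND2_EXCLUDED]
    z, ann = zscore_annotate(sub, r2_sub, markers=markers)
    return ClusterModel(
        round1_labels=r1,
        excluded_clusters=excluded,
        retained_index=retained,
        round2_labels=r2,
        zscores=z,
        annotations=ann,
        params={
            "neighbors": neighbors,
            "seed": seed,
            "round1_resolution": round1_resolution,
            "round2_resolution": res,
        },
    )


# ---------------------------------------------------------------------------
# annotation and abundance analytics
# ---------------------------------------------------------------------------


def zscore_annotate(
    table: EventTable,
    labels: np.ndarray,
    markers: list[str] | None = None,
    use_median: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x marker z-scores and the derived hi/lo designations.

    Per marker, the vector of cluster means (arcsinh scale) is centered
    and scaled across clusters using the population SD (ddof = 0); a
    marker is "hi" in a cluster at z >= 1.5 and "lo" at z <= -1.5.  The
    population convention matters with few clusters: a marker elevated in
    exactly one of K clusters tops out at z = sqrt(K - 1), so the hi rule
    can fire from K = 4 clusters up.  Zero-variance markers get z = 0
    everywhere by convention.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels[~pd.isna(labels)]).astype(int)
    if len(clusters) < 2:
        raise ValueError("z-score annotation needs >= 2 clusters")
    if markers is None:
        markers = table.marker_names()
    agg = np.median if use_median else np.mean
    stat = np.empty((len(clusters), len(markers)))
    for i, c in enumerate(clusters):
        members = labels == c
        for j, m in enumerate(markers):
            stat[i, j] = agg(arcsinh(table.data(m)[members]))
    mu = stat.mean(axis=0)
    sd = stat.std(axis=0)
    z = np.zeros_like(stat)
    nz = sd > 0
    z[:, nz] = (stat[:, nz] - mu[nz]) / sd[nz]
    zscores = pd.DataFrame(z, index=pd.Index(clusters, name="cluster"), columns=markers)
    ann = pd.DataFrame("", index=zscores.index, columns=markers)
    ann = ann.mask(zscores >= HI_Z, "hi").mask(zscores <= LO_Z, "lo")
    return zscores, ann


def abundance_trajectories(
    labels: np.ndarray,
    metadata: pd.DataFrame,
    condition_col: str = "stimulus",
) -> AbundanceTrajectory:
    """Cluster-abundance time courses per condition.

    ``metadata`` must align with ``labels`` and carry ``time_h`` and
    ``replicate`` plus the condition column.  Fractions are computed per
    replicate then averaged; per (condition, time) the cluster fractions
    sum to 1.  The time-normalized layer divides each cluster's series by
    its own sum across time, and clusters are ordered by ascending
    abundance-weighted mean time index, so early-emerging clusters rank
    first.
    """
    labels = np.asarray(labels)
    ok = ~pd.isna(labels)
    df = metadata.loc[ok, [condition_col, "time_h", "replicate"]].copy()
    df["cluster"] = labels[ok].astype(int)
    counts = (
        df.groupby([condition_col, "time_h", "replicate", "cluster"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby([condition_col, "time_h", "replicate"], observed=True)["n"].transform(
        "sum"
    )
    counts["fraction"] = counts["n"] / totals

    clusters = np.sort(df["cluster"].unique())
    fractions: dict[str, pd.DataFrame] = {}
    time_norm: dict[str, pd.DataFrame] = {}
    mean_time_index: dict[int, list[float]] = {c: [] for c in clusters}
    for cond, grp in counts.groupby(condition_col, observed=True):
        mat = (
            grp.pivot_table(
                index="cluster", columns="time_h", values="fraction", aggfunc="mean"
            )
            .reindex(clusters)
            .fillna(0.0)
        )
        # renormalize columns: a cluster absent at a time point is a true 0,
        # but replicate-mean fractions must still sum to 1 per time point
        mat = mat / mat.sum(axis=0)
        fractions[cond] = mat
        row_sums = mat.sum(axis=1)
        tn = mat.div(row_sums.where(row_sums > 0, np.nan), axis=0)
        time_norm[cond] = tn
        t_index = np.arange(mat.shape[1], dtype=float)
        for c in clusters:
            w = tn.loc[c].to_numpy()
            if np.isfinite(w).all() and w.sum() > 0:
                mean_time_index[c].append(float(np.dot(w, t_index)))
    order_stat = pd.Series(
        {c: np.mean(v) if v else np.inf for c, v in mean_time_index.items()}
    ).sort_values(kind="stable")
    ordering = pd.Series(
        np.arange(1, len(order_stat) + 1), index=order_stat.index, name="order"
    )
    return AbundanceTrajectory(
        fractions=fractions,
        replicate_fractions=counts,
        time_normalized=time_norm,
        ordering=ordering.sort_index(),
    )


def rmse_baseline_return(
    traj: AbundanceTrajectory,
    condition: str,
    t_end: float = 48.0,
    t0: float = 0.0,
    scale: str = "fraction",
) -> float:
    """RMSE of cluster-abundance differences between ``t_end`` and ``t0``
    (expected value 0): small values mean the culture's cluster
    composition has returned toward its baseline state.

    ``scale``: ``"fraction"`` (default) or ``"percent"``.
    """
    mat = traj.fractions[condition]
    for t in (t0, t_end):
        if t not in mat.columns:
            raise ValueError(f"time point {t} h missing for condition {condition!r}")
    diff = mat[t_end] - mat[t0]
    rmse = float(np.sqrt(np.mean(np.square(diff.to_numpy()))))
    return rmse * 100.0 if scale == "percent" else rmse


def cluster_fraction(
    labels: np.ndarray,
    metadata: pd.DataFrame,
    cluster: int,
    condition: str | None = None,
    time_h: float | None = None,
    condition_col: str = "stimulus",
) -> float:
    """Fraction of the stratum's labeled events in ``cluster``
    (replicates pooled).  Returns NaN for an empty stratum."""
    labels = np.asarray(labels)
    mask = ~pd.isna(labels)
    if condition is not None:
        mask &= (metadata[condition_col] == condition).to_numpy()
    if time_h is not None:
        mask &= np.isclose(metadata["time_h"].to_numpy(dtype=float), time_h)
    if not mask.any():
        return float("nan")
    return float(np.mean(labels[mask] == cluster))


def embed_umap(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding with the study's parameters: 15 nearest
    neighbors, Euclidean metric, local connectivity 1, 2 components,
    1000 epochs.  Visualization only — no analytics depend on it."""
    import umap  # deferred: numba compilation is slow at import time

    features = np.asarray(features)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if len(features) <= 15:
        raise ValueError("UMAP embedding needs more events than neighbors (15)")
    reducer = umap.UMAP(
        n_neighbors=15,
        metric="euclidean",
        local_connectivity=1,
        n_components=2,
        n_epochs=1000,
        random_state=int(seed),
    )
    return np.asarray(reducer.fit_transform(features))
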