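"""Visualization of clustering results and track dynamics.

Seven plot families: UMAP scatter, cluster-proportion pie, per-cluster
feature-median heatmap, per-cluster violin, sampled cell-outline (ROI) grid,
linearized-track raster ("rag plot") and the physical track overview.

Every function writes a figure file (format chosen by the path's extension)
*and* returns the numeric table underlying the figure — proportions, medians,
orderings — so results stay testable without pixel comparison.  All sampling
is seed-controlled.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # file output only; no display backend required

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import CLUSTER_COLUMN, ClusteringResult, MigrData
from . import dynamics as dyn

__all__ = [
    "plot_umap",
    "plot_pie",
    "plot_heatmap",
    "plot_violin",
    "plot_roi",
    "plot_rag",
    "plot_tracks",
]


def _clustering(data: MigrData) -> ClusteringResult:
    res = data.results.get("clustering")
    if not isinstance(res, ClusteringResult):
        raise ValueError("no clustering result present — run clustering first")
    return res


def _labelled_spots(data: MigrData) -> pd.DataFrame:
    if CLUSTER_COLUMN not in data.spots.columns:
        raise ValueError("no cluster labels on spots — run clustering first")
    return data.spots.dropna(subset=[CLUSTER_COLUMN])


def plot_umap(data: MigrData, colour_by: str = "cluster", path: str = "umap.png") -> pd.DataFrame:
    """Scatter of the UMAP embedding coloured by cluster or by a feature.

    ``colour_by="cluster"`` gives one discrete colour per cluster with a
    legend; any numeric spot feature name gives a continuous colourbar
    (e.g. mapping speed onto the embedding).  Returns the plotted table
    (spot_id, umap_1, umap_2, colour value).
    """
    res = _clustering(data)
    table = pd.DataFrame(
        {
            "spot_id": res.spot_ids,
            "umap_1": res.umap[:, 0],
            "umap_2": res.umap[:, 1],
            "cluster": res.labels,
        }
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    if colour_by == "cluster":
        for c in sorted(np.unique(res.labels)):
            sub = table[table["cluster"] == c]
            ax.scatter(sub["umap_1"], sub["umap_2"], s=8, label=f"cluster {c}")
        ax.legend(markerscale=2, fontsize=8)
    else:
        if colour_by not in data.spots.columns:
            raise KeyError(f"unknown feature {colour_by!r}")
        values = data.spots.set_index("spot_id").loc[table["spot_id"], colour_by]
        table[colour_by] = values.to_numpy()
        sc = ax.scatter(table["umap_1"], table["umap_2"], c=table[colour_by], s=8, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=colour_by)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table


def plot_pie(data: MigrData, path: str = "pie.png") -> pd.Series:
    """Pie chart of spot proportions per cluster; returns the fractions."""
    spots = _labelled_spots(data)
    counts = spots[CLUSTER_COLUMN].astype(int).value_counts().sort_index()
    fractions = counts / counts.sum()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(fractions, labels=[f"cluster {c}" for c in fractions.index], autopct="%.1f%%")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fractions


def plot_heatmap(
    data: MigrData, features: Sequence[str], path: str = "heatmap.png"
) -> pd.DataFrame:
    """Heatmap of per-cluster feature medians.

    Rows are features, columns clusters.  For display each row is min-max
    rescaled over the cluster medians; the *raw* median matrix is returned.
    """
    if not features:
        raise ValueError("empty feature list")
    spots = _labelled_spots(data)
    missing = [f for f in features if f not in spots.columns]
    if missing:
        raise KeyError(f"unknown feature(s) {missing}")
    medians = (
        spots.groupby(spots[CLUSTER_COLUMN].astype(int))[list(features)].median().T
    )
    medians.columns.name = "cluster"
    span = medians.max(axis=1) - medians.min(axis=1)
    display = medians.sub(medians.min(axis=1), axis=0).div(span.replace(0, np.nan), axis=0).fillna(0.5)
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * medians.shape[1], 1 + 0.45 * medians.shape[0]))
    im = ax.imshow(display.to_numpy(), aspect="auto", cmap="magma", vmin=0, vmax=1)
    ax.set_xticks(range(medians.shape[1]), [str(c) for c in medians.columns])
    ax.set_yticks(range(medians.shape[0]), list(medians.index))
    ax.set_xlabel("cluster")
    fig.colorbar(im, ax=ax, label="row-scaled median")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return medians


def plot_violin(data: MigrData, feature: str, path: str = "violin.png") -> pd.DataFrame:
    """Violin plot of one feature's distribution per cluster (ordered by label)."""
    spots = _labelled_spots(data)
    if feature not in spots.columns:
        raise KeyError(f"unknown feature {feature!r}")
    clusters = sorted(spots[CLUSTER_COLUMN].astype(int).unique())
    groups = [
        spots.loc[spots[CLUSTER_COLUMN] == c, feature].dropna().to_numpy() for c in clusters
    ]
    fig, ax = plt.subplots(figsize=(1.5 + 0.8 * len(clusters), 4))
    ax.violinplot(groups, positions=range(1, len(clusters) + 1), showmedians=True)
    ax.set_xticks(range(1, len(clusters) + 1), [str(c) for c in clusters])
    ax.set_xlabel("cluster")
    ax.set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return pd.DataFrame(
        {"cluster": clusters, "n": [g.size for g in groups], "median": [np.median(g) if g.size else np.nan for g in groups]}
    )


def plot_roi(
    data: MigrData, spots_per_cluster: int = 5, seed: int = 0, path: str = "roi.png"
) -> pd.DataFrame:
    """Grid of sampled cell outlines per cluster.

    Draws up to ``spots_per_cluster`` seeded random outlines for each cluster,
    each closed polygon centred at the origin of its grid cell.  Returns the
    sampled (cluster, spot_id) table.
    """
    if not len(data.roi):
        raise ValueError("no roi_points present in this dataset")
    spots = _labelled_spots(data)
    with_roi = spots[spots["spot_id"].isin(set(data.roi["spot_id"]))]
    rng = np.random.default_rng(seed)
    clusters = sorted(with_roi[CLUSTER_COLUMN].astype(int).unique())
    sampled: list[dict] = []
    for c in clusters:
        ids = with_roi.loc[with_roi[CLUSTER_COLUMN] == c, "spot_id"].to_numpy()
        take = rng.choice(ids, size=min(spots_per_cluster, ids.size), replace=False)
        sampled.extend({"cluster": c, "spot_id": int(s)} for s in take)
    table = pd.DataFrame(sampled)

    fig, axes = plt.subplots(
        len(clusters), spots_per_cluster, figsize=(1.6 * spots_per_cluster, 1.6 * len(clusters)),
        squeeze=False,
    )
    for i, c in enumerate(clusters):
        row_ids = table.loc[table["cluster"] == c, "spot_id"].tolist()
        for j in range(spots_per_cluster):
            ax = axes[i][j]
            ax.set_axis_off()
            if j < len(row_ids):
                pts = data.roi_points(row_ids[j])
                closed = np.vstack([pts, pts[:1]])  # close the polygon
                ax.plot(closed[:, 0], closed[:, 1])
                ax.set_aspect("equal")
        axes[i][0].set_title(f"cluster {c}", fontsize=8, loc="left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return table


def plot_rag(
    data: MigrData,
    colour_by: str = "cluster",
    order_by: str = "MEAN_DIRECTIONAL_CHANGE_RATE",
    path: str = "rag.png",
) -> pd.DataFrame:
    """Raster of cluster labels (or a feature) over linearized tracks.

    One column per track, rows are frame indices, so phenotype switches show
    as colour changes along a column and gaps stay blank.  Columns are
    ordered ascending by ``order_by`` (a track feature).  Returns the raster
    as a DataFrame (index = frame, columns = track ids in display order).
    """
    seqs = dyn.track_sequences(data) if colour_by == "cluster" else _feature_sequences(data, colour_by)
    if not seqs:
        raise ValueError("no track sequences to plot")
    order = dyn.order_tracks(seqs, data, by_feature=order_by)
    max_frame = max(max(s.frames) for s in seqs)
    raster = pd.DataFrame(np.nan, index=range(max_frame + 1), columns=order)
    for seq in seqs:
        for frame, lab in zip(seq.frames, seq.labels):
            if lab is not None:
                raster.loc[frame, seq.track_id] = float(lab)
    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(order)), 4))
    cmap = plt.get_cmap("tab10" if colour_by == "cluster" else "viridis").copy()
    cmap.set_bad("white")
    im = ax.imshow(np.ma.masked_invalid(raster.to_numpy()), aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel(f"track (ordered by {order_by})")
    ax.set_ylabel("frame")
    fig.colorbar(im, ax=ax, label=colour_by)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return raster


def _feature_sequences(data: MigrData, feature: str) -> list[dyn.TrackSequence]:
    if feature not in data.spots.columns:
        raise KeyError(f"unknown feature {feature!r}")
    return dyn.track_sequences(data, label_column=feature)


def plot_tracks(
    data: MigrData, colour_by: str | None = None, path: str = "tracks.png", flip_y: bool = True
) -> pd.DataFrame:
    """Overview of all spots connected as physical migration tracks.

    Spots of each track are joined by line segments in frame order on the xy
    plane; with ``colour_by="cluster"`` the spots are coloured by their
    cluster label.  ``flip_y`` uses image-style y-down axes (default); pass
    False for mathematical orientation.  Returns the per-track segment-count
    table.
    """
    if not len(data.spots):
        raise ValueError("no spots to plot")
    spots = data.spots.dropna(subset=["track_id"])
    fig, ax = plt.subplots(figsize=(6, 6))
    seg_counts: list[dict] = []
    for tid, group in spots.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        ax.plot(group["x"], group["y"], lw=0.6, color="0.6", zorder=1)
        seg_counts.append({"track_id": int(tid), "n_segments": len(group) - 1})
    if colour_by == "cluster" and CLUSTER_COLUMN in data.spots.columns:
        lab = spots.dropna(subset=[CLUSTER_COLUMN])
        for c in sorted(lab[CLUSTER_COLUMN].astype(int).unique()):
            sub = lab[lab[CLUSTER_COLUMN] == c]
            ax.scatter(sub["x"], sub["y"], s=6, label=f"cluster {c}", zorder=2)
        ax.legend(markerscale=2, fontsize=8)
    else:
        ax.scatter(spots["x"], spots["y"], s=4, color="tab:blue", zorder=2)
    units = data.meta.get("spatial_units") or "units"
    ax.set_xlabel(f"x ({units})")
    ax.set_ylabel(f"y ({units})")
    if flip_y:
        ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return pd.DataFrame(seg_counts)
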