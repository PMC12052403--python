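"""Phenotype dynamics along migration tracks.

Once every spot carries a cluster label, each track becomes a label sequence
in time.  This module quantifies how stable those sequences are (the
stable-track statistic), how phenotypes flow into one another (the empirical
transition matrix), how tracks should be ordered for linearized display, and
whether a feature differs between one cluster and the rest (rank-sum test).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CLUSTER_COLUMN, MigrData

__all__ = [
    "TrackSequence",
    "track_sequences",
    "stability_fraction",
    "transition_matrix",
    "order_tracks",
    "feature_by_cluster_test",
    "cluster_feature_table",
]


@dataclasses.dataclass
class TrackSequence:
    """Cluster labels of one track's spots, in frame order.

    ``labels`` may contain None where a spot lost its label (e.g. dropped by
    NA handling before clustering); frames are strictly increasing.
    """

    track_id: int
    ordered_spot_ids: list[int]
    labels: list[object]  # label or None
    frames: list[int]

    def labelled(self) -> list[object]:
        return [l for l in self.labels if l is not None]


def track_sequences(data: MigrData, label_column: str = CLUSTER_COLUMN) -> list[TrackSequence]:
    """Build one label sequence per track with at least one labelled spot.

    Spots are ordered by frame; gap frames are simply absent from the
    sequence.  Raises if no labels are present at all (run clustering first).
    """
    if label_column not in data.spots.columns:
        raise ValueError(
            f"no {label_column!r} column on spots — run clustering before track analysis"
        )
    spots = data.spots.dropna(subset=["track_id"])
    out: list[TrackSequence] = []
    for tid, group in spots.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        labels = [None if pd.isna(v) else (int(v) if _is_number(v) else v) for v in group[label_column]]
        if all(l is None for l in labels):
            continue
        out.append(
            TrackSequence(
                track_id=int(tid),
                ordered_spot_ids=[int(s) for s in group["spot_id"]],
                labels=labels,
                frames=[int(f) for f in group["frame"]],
            )
        )
    return out


def _is_number(v: object) -> bool:
    return isinstance(v, (int, float, np.integer, np.floating))


def stability_fraction(
    seqs: Sequence[TrackSequence], threshold: float = 0.5
) -> tuple[float, dict[int, bool]]:
    """Fraction of tracks with a stable phenotype pattern.

    A track is *stable* iff strictly more than ``threshold`` (default 50%) of
    its labelled spots share one cluster label; a 50/50 two-cluster track is
    therefore unstable.  Returns ``(fraction, {track_id: stable})``.
    """
    if not seqs:
        raise ValueError("no track sequences given")
    flags: dict[int, bool] = {}
    for seq in seqs:
        labelled = seq.labelled()
        counts = pd.Series(labelled).value_counts()
        flags[seq.track_id] = bool(counts.iloc[0] / len(labelled) > threshold)
    fraction = sum(flags.values()) / len(flags)
    return fraction, flags


def transition_matrix(
    seqs: Sequence[TrackSequence],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical cluster-to-cluster transition counts along tracks.

    Counts consecutive labelled pairs aggregated over all sequences; pairs
    separated by an unlabelled spot are skipped (a missing label breaks the
    chain rather than acting as a cluster).  Returns ``(counts, row_normalized)``
    DataFrames indexed by source label with columns = destination label; each
    non-empty row of the normalized matrix sums to 1.
    """
    pairs: list[tuple[object, object]] = []
    for seq in seqs:
        prev = None
        prev_pos = None
        for pos, lab in enumerate(seq.labels):
            if lab is None:
                prev = None
                continue
            if prev is not None and prev_pos == pos - 1:
                pairs.append((prev, lab))
            prev = lab
            prev_pos = pos
    if not pairs:
        raise ValueError("no consecutive labelled spot pairs in any sequence")
    labels = sorted({p[0] for p in pairs} | {p[1] for p in pairs})
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=np.int64)
    for a, b in pairs:
        counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    normalized = counts.astype(float).div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return counts, normalized


def order_tracks(
    seqs: Sequence[TrackSequence],
    data: MigrData,
    by_feature: str = "MEAN_DIRECTIONAL_CHANGE_RATE",
) -> list[int]:
    """Track ids sorted ascending by a track feature.

    Ties break by track id; tracks whose feature is missing go last.  This is
    the ordering used for linearized (rag) plots.
    """
    if by_feature not in data.tracks.columns:
        raise KeyError(f"unknown track feature {by_feature!r}")
    feat = data.tracks.set_index("track_id")[by_feature]
    ids = [s.track_id for s in seqs]

    def key(tid: int):
        v = feat.get(tid, np.nan)
        missing = pd.isna(v)
        return (missing, v if not missing else 0.0, tid)

    return sorted(ids, key=key)


def feature_by_cluster_test(
    data: MigrData,
    feature: str,
    cluster: int,
    label_column: str = CLUSTER_COLUMN,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of one cluster vs all other spots.

    Tests whether ``feature`` in the named cluster differs in location from
    the pooled remaining labelled spots.  Uses the exact null distribution
    when both groups have at most 10 observations, otherwise the normal
    approximation with continuity correction.  Returns ``(statistic, p)``
    where the statistic is the Mann-Whitney U of the cluster group.
    """
    if feature not in data.spots.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if label_column not in data.spots.columns:
        raise ValueError("no cluster labels on spots")
    spots = data.spots.dropna(subset=[label_column, feature])
    in_cluster = spots[spots[label_column] == cluster][feature].to_numpy(dtype=float)
    rest = spots[spots[label_column] != cluster][feature].to_numpy(dtype=float)
    if in_cluster.size == 0 or rest.size == 0:
        raise ValueError(
            f"cluster {cluster} has {in_cluster.size} spots and the rest {rest.size}; "
            "both groups must be non-empty"
        )
    method = "exact" if max(in_cluster.size, rest.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(
        in_cluster, rest, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def cluster_feature_table(
    data: MigrData,
    features: Sequence[str],
    label_column: str = CLUSTER_COLUMN,
) -> pd.DataFrame:
    """Rank-sum test of every cluster vs rest for every feature.

    Returns a long-format table (cluster, feature, statistic, p, p_adjusted)
    with Benjamini-Hochberg adjusted p-values alongside the raw ones.
    """
    if label_column not in data.spots.columns:
        raise ValueError("no cluster labels on spots")
    clusters = sorted(int(c) for c in data.spots[label_column].dropna().unique())
    rows = []
    for feature in features:
        for c in clusters:
            stat, p = feature_by_cluster_test(data, feature, c, label_column)
            rows.append({"cluster": c, "feature": feature, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
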