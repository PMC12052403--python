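"""Iterative Clustering Projection (ICP) ensemble clustering.

ICP is a self-learning loop that turns an unlabelled feature matrix into a
soft clustering without assuming any parametric cluster shape:

1. assign each cell a uniformly random cluster label out of ``k``;
2. draw a stratified sample of 30% of the cells of each current cluster and
   fit an L1-regularized multinomial logistic regression on it;
3. predict labels and class probabilities for *all* cells, giving a proposed
   partition S';
4. accept S <- S' iff the adjusted Rand index between S' and S exceeds the
   best ARI seen so far (starting from 0); otherwise keep S.

Steps 2-4 repeat until a run of consecutive rejections or an iteration cap.
Because acceptance requires strictly increasing agreement between model and
prediction, the loop converges toward a partition the sparse classifier can
reproduce from a subsample — clusters supported by discriminative features.

An ensemble of independently seeded ICP runs yields one N x k probability
matrix each; these are concatenated column-wise and summarized by PCA
("consensus PCA"), on which Ward hierarchical clustering produces the final
partition at a user-chosen number of clusters, and UMAP a 2-D view.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from joblib import Parallel, delayed
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .data import CLUSTER_COLUMN, ClusteringResult, MigrData

logger = logging.getLogger("migroclust")

__all__ = [
    "FeatureMatrix",
    "ICPConfig",
    "ICPRunResult",
    "ICPError",
    "prepare_features",
    "adjusted_rand_index",
    "icp_single_run",
    "icp_ensemble",
    "consensus_pca",
    "ward_cut",
    "umap_embed",
    "cluster",
]


class ICPError(Exception):
    """Raised when an ICP run cannot proceed (degenerate data, failed retries)."""


@dataclasses.dataclass
class FeatureMatrix:
    """Numeric matrix of spots x features, ready for clustering.

    ``values`` is dense, finite, and feature-wise standardized; ``spot_ids``
    maps rows back to the spots table.
    """

    values: np.ndarray
    spot_ids: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.spot_ids) != self.values.shape[0]:
            raise ValueError("spot_ids length does not match matrix rows")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class ICPConfig:
    """Hyperparameters of the ICP ensemble.

    Parameters
    ----------
    n_runs : int
        Ensemble size L (independent ICP runs). Default 50.
    k : int
        Number of clusters per ICP run. Default 15.  This is deliberately
        larger than the expected number of phenotypes: the consensus step
        aggregates the over-segmented runs and the final K is chosen at the
        dendrogram cut.
    n_components : int
        PCA dimension p of the consensus space (capped at L*k and N-1).
    reg_strength : float
        Inverse L1-regularization strength C of the logistic model.
    train_fraction : float
        Fraction of each cluster sampled for training (ceil, min 1). The
        loop's only fixed constant; 0.3 by construction of the method.
    max_iterations, max_stalls : int
        Stop after ``max_iterations`` total or ``max_stalls`` consecutive
        non-improving iterations, whichever comes first.
    min_cluster_size : int
        Required minimum initial cluster size (N >= k * min_cluster_size).
    max_retries : int
        Reseeds allowed when a run's model collapses below 2 predicted labels.
    na_policy : str
        ``"drop"`` rows with missing features (default) or ``"impute"`` with
        the feature median.
    umap_n_neighbors, umap_min_dist : UMAP hyperparameters.
    n_jobs : int
        Parallel workers for the ensemble; results are seed-determined and
        identical to sequential execution.
    lr_max_iter, lr_tol : solver budget of each logistic fit.
    """

    n_runs: int = 50
    k: int = 15
    n_components: int = 50
    reg_strength: float = 0.3
    train_fraction: float = 0.3
    max_iterations: int = 200
    max_stalls: int = 5
    min_cluster_size: int = 2
    max_retries: int = 3
    na_policy: str = "drop"
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    n_jobs: int = 1
    lr_max_iter: int = 200
    lr_tol: float = 1e-4

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ICPRunResult:
    """One ICP run: soft assignment, final partition and acceptance trace."""

    probabilities: np.ndarray  # (N, k), rows sum to 1
    final_partition: np.ndarray  # (N,) labels in 1..k
    ari_trace: list[float]  # accepted ARI values, strictly increasing
    n_iterations: int
    seed: int


# ----------------------------------------------------------------- features


def prepare_features(
    data: MigrData,
    feature_names: Sequence[str],
    na_policy: str = "drop",
) -> FeatureMatrix:
    """Assemble and standardize the selected spot features.

    Rows with missing values are dropped (``na_policy="drop"``) or median-
    imputed (``"impute"``); each remaining column is then z-scored (mean 0,
    sample standard deviation 1).  Zero-variance columns are removed with a
    warning — they carry no clustering signal and would divide by zero.
    """
    if na_policy not in ("drop", "impute"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    available = [c for c in data.spots.columns if c != "spot_id"]
    missing = [f for f in feature_names if f not in data.spots.columns]
    if missing:
        raise KeyError(f"unknown feature(s) {missing}; available: {sorted(available)}")
    if len(data.spots) < 2:
        raise ValueError("need at least 2 spots to build a feature matrix")

    sub = data.spots[["spot_id", *feature_names]].copy()
    if na_policy == "drop":
        sub = sub.dropna(subset=list(feature_names))
    else:
        for f in feature_names:
            sub[f] = sub[f].fillna(sub[f].median())
    values = sub[list(feature_names)].to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows after NA handling")

    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"removed zero-variance feature(s): {dropped}")
    if not keep.any():
        raise ValueError("all selected features have zero variance")
    values = values[:, keep]
    values = (values - values.mean(axis=0)) / sd[keep]
    return FeatureMatrix(
        values=values,
        spot_ids=sub["spot_id"].to_numpy(),
        feature_names=[f for f, k in zip(feature_names, keep) if k],
    )


# ---------------------------------------------------------------------- ARI


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Chance-corrected pair-counting agreement: 1 for identical partitions (up
    to relabeling), ~0 for independent ones.  When the correction denominator
    vanishes (both partitions all-singletons or all-one-cluster in the ways
    that zero the denominator) the index is defined as 1 if the numerator is
    also 0, matching the limit of perfect agreement.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x: np.ndarray) -> float:
        x = x.astype(np.float64)
        return float((x * (x - 1) / 2).sum())

    sum_ij = comb2(contingency.ravel())
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    numer = sum_ij - expected
    if denom == 0:
        return 1.0 if numer == 0 else 0.0
    return numer / denom


# ----------------------------------------------------------------- ICP loop


def _fit_predict(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    rng: np.random.Generator,
    config: ICPConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 30% subsample -> L1 logistic fit -> predict all cells.

    Returns (predicted labels in 1..k, (N, k) probability matrix).  Classes
    absent from the training sample get zero probability columns.
    """
    train_idx: list[np.ndarray] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n_take = max(1, math.ceil(config.train_fraction * members.size))
        train_idx.append(rng.choice(members, size=n_take, replace=False))
    idx = np.concatenate(train_idx)

    model = LogisticRegression(
        penalty="l1",
        C=config.reg_strength,
        solver="saga",
        max_iter=config.lr_max_iter,
        tol=config.lr_tol,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence warnings on tiny fits
        model.fit(X[idx], labels[idx])
    proba_present = model.predict_proba(X)
    proba = np.zeros((X.shape[0], k))
    for j, c in enumerate(model.classes_):
        proba[:, int(c) - 1] = proba_present[:, j]
    predicted = model.classes_[np.argmax(proba_present, axis=1)]
    return predicted.astype(np.int64), proba


def icp_single_run(X: FeatureMatrix, k: int, seed: int, config: ICPConfig | None = None) -> ICPRunResult:
    """Run one ICP loop on a prepared feature matrix.

    Labels are integers 1..k.  The returned probabilities come from the last
    *accepted* model; the acceptance trace is strictly increasing by
    construction.  A run whose classifier collapses to a single predicted
    label is restarted with the next seed, up to ``config.max_retries`` times.
    """
    config = config or ICPConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.n < k * config.min_cluster_size:
        raise ICPError(
            f"N={X.n} too small for k={k} clusters of minimum size {config.min_cluster_size}"
        )

    result: ICPRunResult | None = None
    for attempt in range(config.max_retries + 1):
        run_seed = seed + attempt * 100_003  # deterministic reseed offset
        result = _icp_attempt(X, k, seed, run_seed, config)
        if result.ari_trace:  # at least one accepted model: a real clustering
            return result
    # every attempt was degenerate (classifier never improved on the random
    # start, e.g. identical feature rows): terminate cleanly with the last
    # attempt's soft assignment rather than raising
    assert result is not None
    return result


def _icp_attempt(X: FeatureMatrix, k: int, seed: int, run_seed: int, config: ICPConfig) -> ICPRunResult:
    rng = np.random.default_rng(run_seed)
    n = X.n
    labels = rng.integers(1, k + 1, size=n).astype(np.int64)

    best_ari = 0.0
    best_proba: np.ndarray | None = None
    best_labels: np.ndarray | None = None
    ari_trace: list[float] = []
    stalls = 0
    iterations = 0
    first_proba: np.ndarray | None = None

    while iterations < config.max_iterations and stalls < config.max_stalls:
        iterations += 1
        predicted, proba = _fit_predict(X.values, labels, k, rng, config)
        if first_proba is None:
            first_proba = proba
        if np.unique(predicted).size < 2:
            # a constant prediction can never be accepted (its ARI to any
            # partition is <= 0); count it as a stalled iteration
            stalls += 1
            continue
        ari = adjusted_rand_index(predicted, labels)
        if ari > best_ari:
            best_ari = ari
            best_proba = proba
            best_labels = predicted
            ari_trace.append(float(ari))
            labels = predicted
            stalls = 0
        else:
            stalls += 1

    if best_proba is None:
        # degenerate input: no proposal ever improved on the random start
        best_proba = first_proba if first_proba is not None else np.full((n, k), 1.0 / k)
        best_labels = labels
    return ICPRunResult(
        probabilities=best_proba,
        final_partition=np.asarray(best_labels, dtype=np.int64),
        ari_trace=ari_trace,
        n_iterations=iterations,
        seed=seed,
    )


def icp_ensemble(
    X: FeatureMatrix,
    k: int,
    L: int,
    base_seed: int,
    config: ICPConfig | None = None,
) -> list[ICPRunResult]:
    """Run L independent ICP runs with seeds ``base_seed .. base_seed+L-1``.

    Runs are seed-determined, so parallel execution (``config.n_jobs``)
    returns exactly the sequential result.
    """
    config = config or ICPConfig()
    if L < 1:
        raise ValueError("ensemble size L must be >= 1")
    seeds = [base_seed + i for i in range(L)]
    if config.n_jobs == 1:
        results = []
        for i, s in enumerate(seeds):
            try:
                results.append(icp_single_run(X, k, s, config))
            except ICPError as exc:
                raise ICPError(f"run {i} (seed {s}) failed: {exc}") from exc
    else:
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(icp_single_run)(X, k, s, config) for s in seeds
        )
    for r in results:
        logger.info(
            "ICP run seed=%d: %d iterations, final ARI %.4f",
            r.seed,
            r.n_iterations,
            r.ari_trace[-1] if r.ari_trace else float("nan"),
        )
    return results


# ------------------------------------------------------------ consensus step


def consensus_pca(runs: Iterable[ICPRunResult], p: int) -> np.ndarray:
    """PCA scores of the column-concatenated ensemble probability matrices.

    The L probability matrices (N x k each) are concatenated to N x (L*k),
    columns centered, and the top-``p`` principal component scores returned
    in decreasing explained-variance order.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one ICP run")
    ns = {r.probabilities.shape[0] for r in runs}
    if len(ns) != 1:
        raise ValueError(f"inconsistent N across runs: {sorted(ns)}")
    concat = np.hstack([r.probabilities for r in runs])
    p_eff = min(p, concat.shape[1], concat.shape[0] - 1)
    if p_eff < 1:
        raise ValueError("cannot compute fewer than 1 principal component")
    pca = PCA(n_components=p_eff, svd_solver="full")
    return pca.fit_transform(concat)


def ward_cut(scores: np.ndarray, k_final: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of the consensus scores, cut at ``k_final``.

    Returns ``(labels, linkage)``.  Labels are re-indexed 1..K by decreasing
    cluster size (ties broken by smallest original label) so cluster 1 is
    always the largest; the scipy linkage matrix is returned for re-cutting.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not 2 <= k_final <= n:
        raise ValueError(f"k_final must be in [2, {n}], got {k_final}")
    linkage = sch.linkage(scores, method="ward")
    raw = sch.fcluster(linkage, t=k_final, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.asarray([remap[c] for c in raw], dtype=np.int64)
    return labels, linkage


def umap_embed(
    scores: np.ndarray,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D UMAP embedding of the consensus scores, deterministic per seed."""
    import umap  # deferred: numba compilation is slow at import time

    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 10:
        raise ValueError(
            f"N={n} is too small for a meaningful UMAP embedding; "
            "scatter the first two PCA score columns directly instead"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(scores), dtype=float)


# -------------------------------------------------------------------- driver


def cluster(
    data: MigrData,
    feature_names: Sequence[str],
    k_final: int,
    config: ICPConfig | None = None,
    seed: int = 0,
) -> MigrData:
    """Full consensus clustering pipeline on a migration dataset.

    prepare_features -> icp_ensemble -> consensus_pca -> ward_cut ->
    umap_embed.  The :class:`ClusteringResult` is stored in the ``results``
    slot under ``"clustering"`` and the final labels are attached to the spots
    table as the ``CLUSTER`` column (NaN for spots dropped by NA handling).
    Fully deterministic given (data, features, seed, config).
    """
    config = config or ICPConfig()

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    X = _stage("prepare_features", prepare_features, data, feature_names, config.na_policy)
    runs = _stage("icp_ensemble", icp_ensemble, X, config.k, config.n_runs, seed, config)
    scores = _stage("consensus_pca", consensus_pca, runs, config.n_components)
    labels, linkage = _stage("ward_cut", ward_cut, scores, k_final)
    coords = _stage(
        "umap_embed", umap_embed, scores, seed, config.umap_n_neighbors, config.umap_min_dist
    )

    result = ClusteringResult(
        spot_ids=X.spot_ids,
        pca_scores=scores,
        linkage=linkage,
        labels=labels,
        umap=coords,
        config={
            **config.to_dict(),
            "feature_names": list(feature_names),
            "used_features": X.feature_names,
            "k_final": int(k_final),
            "seed": int(seed),
        },
    )
    out = data.copy()
    out.results["clustering"] = result
    label_map = dict(zip(X.spot_ids.tolist(), labels.tolist()))
    out.spots[CLUSTER_COLUMN] = out.spots["spot_id"].map(label_map)
    return out
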