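"""Feature preparation, ARI, the ICP loop, consensus PCA, Ward cut and UMAP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

import migroclust as mc

from conftest import ari_bruteforce, make_small_migrdata


class TestPrepareFeatures:
    def test_zscore_of_arithmetic_sequence(self):
        data = make_small_migrdata()
        data.spots["F"] = [1.0, 2.0, 3.0]
        fm = mc.prepare_features(data, ["F"])
        assert fm.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_removed_with_warning(self):
        data = make_small_migrdata()
        data.spots["F"] = [1.0, 2.0, 3.0]
        data.spots["CONST"] = 7.0
        with pytest.warns(UserWarning, match="CONST"):
            fm = mc.prepare_features(data, ["F", "CONST"])
        assert fm.feature_names == ["F"]

    def test_na_drop_removes_rows(self):
        data = make_small_migrdata()
        extra = data.spots.iloc[[0, 1]].copy()
        extra["spot_id"] = [4, 5]
        data.spots = pd.concat([data.spots, extra], ignore_index=True)
        data.spots["F"] = [1.0, 2.0, 3.0, np.nan, 5.0]
        data.spots["G"] = [1.0, 1.0, 2.0, 2.0, 3.0]
        fm = mc.prepare_features(data, ["F", "G"], na_policy="drop")
        assert fm.n == 4

    def test_na_impute_keeps_rows(self):
        data = make_small_migrdata()
        data.spots["F"] = [1.0, np.nan, 3.0]
        fm = mc.prepare_features(data, ["F"], na_policy="impute")
        assert fm.n == 3

    def test_unknown_feature_lists_available(self):
        with pytest.raises(KeyError, match="NOPE"):
            mc.prepare_features(make_small_migrdata(), ["NOPE"])

    def test_all_zero_variance_is_error(self):
        data = make_small_migrdata()
        data.spots["C"] = 1.0
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero variance"):
                mc.prepare_features(data, ["C"])


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert mc.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert mc.adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_one_cluster_vs_singletons(self):
        assert mc.adjusted_rand_index([1] * 5, [1, 2, 3, 4, 5]) == 0.0

    def test_worked_example(self):
        # 1.2 / 3.7 from direct pair counting over C(6,2) pairs
        v = mc.adjusted_rand_index([1, 1, 1, 2, 2, 2], [1, 1, 2, 2, 2, 2])
        assert v == pytest.approx(1.2 / 3.7, abs=1e-12)
        assert v == pytest.approx(ari_bruteforce([1, 1, 1, 2, 2, 2], [1, 1, 2, 2, 2, 2]), abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mc.adjusted_rand_index([1, 2], [1, 2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 12),
        seed=st.integers(0, 10_000),
        ka=st.integers(1, 4),
        kb=st.integers(1, 4),
    )
    def test_matches_bruteforce_and_is_symmetric(self, n, seed, ka, kb):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, ka, size=n)
        b = rng.integers(0, kb, size=n)
        ours = mc.adjusted_rand_index(a, b)
        assert ours == pytest.approx(ari_bruteforce(a, b), abs=1e-12)
        assert ours == pytest.approx(mc.adjusted_rand_index(b, a), abs=1e-15)
        # relabeling invariance
        remap = {v: 10 - v for v in np.unique(a)}
        assert mc.adjusted_rand_index([remap[v] for v in a], b) == pytest.approx(ours, abs=1e-15)

    def test_agrees_with_sklearn_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 4, size=30)
            assert mc.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestICPRun:
    def test_blob_recovery_at_locking_seed(self, blob_matrix):
        # the loop locks onto the inter-blob gap at this seed; recovery of the
        # generating labels is then exact (see also the consensus-pipeline test,
        # which recovers the blobs regardless of per-run seed luck)
        fm, truth = blob_matrix
        run = mc.icp_single_run(fm, 2, seed=2, config=mc.ICPConfig())
        assert mc.adjusted_rand_index(run.final_partition, truth) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_run_invariants(self, blob_matrix, seed):
        fm, _ = blob_matrix
        run = mc.icp_single_run(fm, 4, seed=seed, config=mc.ICPConfig())
        assert run.probabilities.shape == (fm.n, 4)
        assert np.allclose(run.probabilities.sum(axis=1), 1.0, atol=1e-8)
        trace = run.ari_trace
        assert all(b > a for a, b in zip(trace, trace[1:]))  # strictly increasing
        assert all(-1.0 <= v <= 1.0 for v in trace)
        assert set(np.unique(run.final_partition)) <= set(range(1, 5))

    def test_identical_rows_terminate_without_exception(self):
        fm = mc.FeatureMatrix(np.zeros((40, 3)), np.arange(40), ["a", "b", "c"])
        run = mc.icp_single_run(fm, 2, seed=0, config=mc.ICPConfig())
        assert run.ari_trace == []  # nothing ever improved on the random start
        assert run.probabilities.shape == (40, 2)

    def test_too_few_cells_for_k_rejected(self):
        fm = mc.FeatureMatrix(np.random.default_rng(0).normal(size=(5, 2)), np.arange(5), ["a", "b"])
        with pytest.raises(mc.ICPError):
            mc.icp_single_run(fm, 4, seed=0, config=mc.ICPConfig(min_cluster_size=2))

    def test_k_below_two_rejected(self, blob_matrix):
        fm, _ = blob_matrix
        with pytest.raises(ValueError):
            mc.icp_single_run(fm, 1, seed=0)


class TestEnsemble:
    def test_single_run_consistency(self, blob_matrix):
        fm, _ = blob_matrix
        cfg = mc.ICPConfig()
        ens = mc.icp_ensemble(fm, 4, L=1, base_seed=7, config=cfg)
        solo = mc.icp_single_run(fm, 4, seed=7, config=cfg)
        assert len(ens) == 1
        assert np.array_equal(ens[0].final_partition, solo.final_partition)
        assert ens[0].ari_trace == solo.ari_trace

    def test_determinism_bitwise(self, blob_matrix):
        fm, _ = blob_matrix
        cfg = mc.ICPConfig()
        a = mc.icp_ensemble(fm, 4, L=3, base_seed=0, config=cfg)
        b = mc.icp_ensemble(fm, 4, L=3, base_seed=0, config=cfg)
        for ra, rb in zip(a, b):
            assert ra.ari_trace == rb.ari_trace
            assert np.array_equal(ra.probabilities, rb.probabilities)
            assert np.array_equal(ra.final_partition, rb.final_partition)

    def test_consensus_recovers_blobs(self, blob_matrix):
        fm, truth = blob_matrix
        runs = mc.icp_ensemble(fm, 15, L=8, base_seed=0, config=mc.ICPConfig())
        scores = mc.consensus_pca(runs, 50)
        labels, _ = mc.ward_cut(scores, 2)
        assert mc.adjusted_rand_index(labels, truth) == 1.0


class TestConsensusPCA:
    def test_duplicate_rows_map_to_equal_scores(self):
        run = mc.ICPRunResult(
            probabilities=np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            final_partition=np.array([1, 1, 2]),
            ari_trace=[0.5],
            n_iterations=1,
            seed=0,
        )
        scores = mc.consensus_pca([run], 1)
        assert scores[0, 0] == pytest.approx(scores[1, 0])
        assert abs(scores[2, 0] - scores[0, 0]) > 0.1

    def test_explained_variance_non_increasing(self, blob_matrix):
        fm, _ = blob_matrix
        runs = mc.icp_ensemble(fm, 4, L=3, base_seed=0, config=mc.ICPConfig())
        scores = mc.consensus_pca(runs, 12)
        variances = scores.var(axis=0)
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_full_rank_scores_preserve_distances(self):
        rng = np.random.default_rng(0)
        proba = rng.dirichlet(np.ones(3), size=20)
        run = mc.ICPRunResult(proba, np.argmax(proba, 1) + 1, [0.5], 1, 0)
        scores = mc.consensus_pca([run], 3)
        centered = proba - proba.mean(axis=0)
        assert pdist(scores) == pytest.approx(pdist(centered), abs=1e-9)

    def test_inconsistent_n_rejected(self):
        r1 = mc.ICPRunResult(np.ones((3, 2)) / 2, np.ones(3, int), [0.5], 1, 0)
        r2 = mc.ICPRunResult(np.ones((4, 2)) / 2, np.ones(4, int), [0.5], 1, 1)
        with pytest.raises(ValueError, match="inconsistent"):
            mc.consensus_pca([r1, r2], 2)


class TestWardCut:
    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(12, 3))
        labels, _ = mc.ward_cut(scores, 12)
        assert len(set(labels.tolist())) == 12

    def test_three_blob_recovery(self):
        rng = np.random.default_rng(0)
        scores = np.vstack(
            [rng.normal(c, 1.0, size=(50, 2)) for c in ((0, 0), (8, 0), (0, 8))]
        )
        truth = np.repeat([0, 1, 2], 50)
        labels, _ = mc.ward_cut(scores, 3)
        assert mc.adjusted_rand_index(labels, truth) == 1.0

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(1)
        _, linkage = mc.ward_cut(rng.normal(size=(30, 4)), 3)
        heights = linkage[:, 2]
        assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(0)
        scores = np.vstack([rng.normal(0, 0.5, (40, 2)), rng.normal(10, 0.5, (10, 2))])
        labels, _ = mc.ward_cut(scores, 2)
        assert (labels[:40] == 1).all()  # biggest cluster gets label 1
        assert (labels[40:] == 2).all()

    def test_out_of_range_k_rejected(self):
        scores = np.random.default_rng(0).normal(size=(10, 2))
        for bad in (1, 11):
            with pytest.raises(ValueError):
                mc.ward_cut(scores, bad)


class TestUMAP:
    def test_shape_finite_and_deterministic(self, blob_matrix):
        fm, _ = blob_matrix
        a = mc.umap_embed(fm.values, seed=5)
        b = mc.umap_embed(fm.values, seed=5)
        assert a.shape == (fm.n, 2)
        assert np.isfinite(a).all()
        assert np.array_equal(a, b)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError, match="PCA"):
            mc.umap_embed(np.zeros((5, 2)), seed=0)

    def test_neighbour_purity_on_three_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 1.0, size=(50, 3)) for c in (0, 8, 16)])
        truth = np.repeat([0, 1, 2], 50)
        emb = mc.umap_embed(X, seed=0)
        nn = NearestNeighbors(n_neighbors=11).fit(emb)
        _, idx = nn.kneighbors(emb)
        pure = 0
        for i in range(len(X)):
            neigh = truth[idx[i, 1:]]
            majority = np.bincount(neigh).argmax()
            pure += majority == truth[i]
        assert pure / len(X) >= 0.9


class TestClusterDriver:
    def test_benchmark_recovery(self, clustered_benchmark):
        data, truth = clustered_benchmark
        res = data.results["clustering"]
        truth_labels = np.array([truth.spot_labels[s] for s in res.spot_ids])
        assert mc.adjusted_rand_index(res.labels, truth_labels) >= 0.9

    def test_config_echoed_and_labels_attached(self, clustered_benchmark):
        data, _ = clustered_benchmark
        res = data.results["clustering"]
        assert res.config["n_runs"] == 8
        assert res.config["k_final"] == 3
        assert res.config["seed"] == 1
        assert res.config["feature_names"] == mc.BENCHMARK_FEATURES
        labelled = data.spots[mc.CLUSTER_COLUMN].dropna()
        assert set(labelled.astype(int)) == {1, 2, 3}

    def test_determinism_of_small_pipeline(self):
        data, _ = mc.simulate(
            mc.SimConfig(
                n_tracks=4,
                track_length=20,
                phenotypes=[
                    mc.PhenotypeSpec(
                        label=i + 1,
                        feature_means={"AREA": 100.0 + 80 * i, "CIRCULARITY": 0.4 + 0.2 * i},
                        feature_sds={"AREA": 10.0, "CIRCULARITY": 0.04},
                        speed_mean=0.4 + 0.4 * i,
                        speed_sd=0.1,
                    )
                    for i in range(2)
                ],
                seed=5,
            )
        )
        data = mc.augment_spot_motility(data)
        cfg = mc.ICPConfig(n_runs=2, k=5, n_components=8)
        a = mc.cluster(data, ["AREA", "CIRCULARITY", "SPEED"], 2, cfg, seed=3)
        b = mc.cluster(data, ["AREA", "CIRCULARITY", "SPEED"], 2, cfg, seed=3)
        ra, rb = a.results["clustering"], b.results["clustering"]
        assert np.array_equal(ra.labels, rb.labels)
        assert np.array_equal(ra.umap, rb.umap)
        assert a.spots[mc.CLUSTER_COLUMN].tolist() == b.spots[mc.CLUSTER_COLUMN].tolist()

    def test_stage_name_in_errors(self):
        data = make_small_migrdata()
        with pytest.raises(KeyError, match="prepare_features"):
            mc.cluster(data, ["NOPE"], 2, mc.ICPConfig(), seed=0)
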