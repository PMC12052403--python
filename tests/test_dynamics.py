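"""Track sequences, stability statistic, transitions, ordering and rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import migroclust as mc
from migroclust.dynamics import TrackSequence

from conftest import make_small_migrdata, ranksum_exact_p


def seq(track_id, labels, frames=None):
    frames = frames if frames is not None else list(range(len(labels)))
    return TrackSequence(
        track_id=track_id,
        ordered_spot_ids=list(range(len(labels))),
        labels=list(labels),
        frames=frames,
    )


class TestTrackSequences:
    def test_frame_ordering(self):
        data = make_small_migrdata()
        data.spots = data.spots.iloc[[2, 0, 1]].reset_index(drop=True)  # shuffle rows
        data.spots[mc.CLUSTER_COLUMN] = [1.0, 1.0, 2.0]
        seqs = mc.track_sequences(data)
        assert len(seqs) == 1
        assert seqs[0].frames == [0, 1, 2]
        assert seqs[0].ordered_spot_ids == [1, 2, 3]

    def test_requires_labels(self):
        with pytest.raises(ValueError, match="clustering"):
            mc.track_sequences(make_small_migrdata())

    def test_fully_unlabelled_track_excluded(self):
        data = make_small_migrdata()
        data.spots[mc.CLUSTER_COLUMN] = np.nan
        assert mc.track_sequences(data) == []

    def test_count_matches_labelled_tracks(self, clustered_benchmark):
        data, _ = clustered_benchmark
        seqs = mc.track_sequences(data)
        labelled = data.spots.dropna(subset=[mc.CLUSTER_COLUMN, "track_id"])
        assert len(seqs) == labelled["track_id"].nunique()


class TestStability:
    def test_forced_flag_set(self):
        # >50% strictly: 3/4 stable, 1/4 unstable, 2/4 (=50%) unstable
        seqs = [seq(1, "AAAB"), seq(2, "ABCD"), seq(3, "AABB")]
        fraction, flags = mc.stability_fraction(seqs)
        assert flags == {1: True, 2: False, 3: False}
        assert fraction == pytest.approx(1 / 3)

    def test_single_label_tracks_all_stable(self):
        fraction, _ = mc.stability_fraction([seq(1, "AAA"), seq(2, "BB")])
        assert fraction == 1.0

    def test_threshold_zero_and_one_limits(self):
        seqs = [seq(1, "AB"), seq(2, "AA")]
        assert mc.stability_fraction(seqs, threshold=0.0)[0] == 1.0
        _, flags = mc.stability_fraction(seqs, threshold=1.0)
        assert flags == {1: False, 2: False}  # strict > 1 never holds

    def test_missing_labels_skipped(self):
        fraction, flags = mc.stability_fraction([seq(1, ["A", None, "A", "B"])])
        assert flags[1] is True  # 2/3 labelled spots in A

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mc.stability_fraction([])

    def test_switchfree_truth_labels_are_fully_stable(self):
        config = mc.SimConfig(
            n_tracks=10,
            track_length=12,
            phenotypes=[
                mc.PhenotypeSpec(
                    label=i + 1,
                    feature_means={"AREA": 100.0 + 100 * i},
                    feature_sds={"AREA": 10.0},
                    speed_mean=0.5,
                    speed_sd=0.1,
                )
                for i in range(3)
            ],
            switch_prob=0.0,
            seed=11,
        )
        data, truth = mc.simulate(config)
        data = mc.attach_spot_annotation(data, mc.CLUSTER_COLUMN, truth.spot_labels)
        fraction, _ = mc.stability_fraction(mc.track_sequences(data))
        assert fraction == 1.0


class TestTransitions:
    def test_single_sequence_counts_and_normalization(self):
        counts, norm = mc.transition_matrix([seq(1, "AAB")])
        assert counts.loc["A", "A"] == 1
        assert counts.loc["A", "B"] == 1
        assert norm.loc["A"].tolist() == [0.5, 0.5]

    def test_nonempty_rows_sum_to_one(self, clustered_benchmark):
        data, _ = clustered_benchmark
        counts, norm = mc.transition_matrix(mc.track_sequences(data))
        row_sums = norm.sum(axis=1)
        nonempty = counts.sum(axis=1) > 0
        assert row_sums[nonempty].to_numpy() == pytest.approx(1.0)
        assert int(counts.to_numpy().sum()) == sum(
            _labelled_pair_count(s) for s in mc.track_sequences(data)
        )

    def test_missing_label_breaks_the_chain(self):
        counts, _ = mc.transition_matrix([seq(1, ["A", None, "B", "B"])])
        # A->B across the gap is not counted; only the direct B->B pair is
        assert "A" not in counts.index or counts.loc["A"].sum() == 0
        assert counts.loc["B", "B"] == 1

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            mc.transition_matrix([seq(1, ["A"])])

    def test_markov_recovery_on_truth_labels(self):
        switch = np.array([[0.0, 0.8, 0.2], [0.5, 0.0, 0.5], [0.1, 0.9, 0.0]])
        config = mc.SimConfig(
            n_tracks=30,
            track_length=250,
            phenotypes=[
                mc.PhenotypeSpec(
                    label=i + 1,
                    feature_means={"AREA": 100.0 + 100 * i},
                    feature_sds={"AREA": 10.0},
                    speed_mean=0.5,
                    speed_sd=0.1,
                )
                for i in range(3)
            ],
            switch_prob=0.2,
            switch_matrix=switch,
            seed=4,
        )
        data, truth = mc.simulate(config)
        data = mc.attach_spot_annotation(data, mc.CLUSTER_COLUMN, truth.spot_labels)
        _, empirical = mc.transition_matrix(mc.track_sequences(data))
        expected = config.effective_transition_matrix()
        assert np.abs(empirical.to_numpy() - expected).max() < 0.05


def _labelled_pair_count(s):
    pairs = 0
    for a, b in zip(s.labels, s.labels[1:]):
        pairs += a is not None and b is not None
    return pairs


class TestOrderTracks:
    def _data_with_feature(self, values):
        tracks = pd.DataFrame(
            {
                "track_id": sorted(values),
                "filtered_in": True,
                "MEAN_DIRECTIONAL_CHANGE_RATE": [values[t] for t in sorted(values)],
            }
        )
        data = mc.MigrData(tracks=tracks, validate=False)
        seqs = [seq(t, "A") for t in sorted(values)]
        return data, seqs

    def test_ascending_order(self):
        data, seqs = self._data_with_feature({1: 0.3, 2: 0.1, 3: 0.2})
        assert mc.order_tracks(seqs, data) == [2, 3, 1]

    def test_ties_break_by_track_id(self):
        data, seqs = self._data_with_feature({3: 0.5, 1: 0.5, 2: 0.5})
        assert mc.order_tracks(seqs, data) == [1, 2, 3]

    def test_missing_value_goes_last(self):
        data, seqs = self._data_with_feature({1: 0.3, 2: np.nan, 3: 0.1})
        assert mc.order_tracks(seqs, data) == [3, 1, 2]

    def test_unknown_feature_rejected(self):
        data, seqs = self._data_with_feature({1: 0.1})
        with pytest.raises(KeyError, match="NOPE"):
            mc.order_tracks(seqs, data, by_feature="NOPE")


class TestFeatureByClusterTest:
    def _data(self, cluster_values, rest_values):
        n = len(cluster_values) + len(rest_values)
        spots = pd.DataFrame(
            {
                "spot_id": range(n),
                "frame": 0,
                "t": 0.0,
                "x": 0.0,
                "y": 0.0,
                "track_id": np.nan,
                "visible": True,
                "F": list(cluster_values) + list(rest_values),
                mc.CLUSTER_COLUMN: [1.0] * len(cluster_values) + [2.0] * len(rest_values),
            }
        )
        return mc.MigrData(spots=spots, validate=False)

    def test_exact_p_matches_enumeration(self):
        data = self._data([10, 11, 12], [1, 2, 3])
        _, p = mc.feature_by_cluster_test(data, "F", 1)
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(ranksum_exact_p([10, 11, 12], [1, 2, 3]), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        data = self._data([1, 2, 3], [1, 2, 3])
        _, p = mc.feature_by_cluster_test(data, "F", 1)
        assert p == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 1, size=8).tolist()
        b = rng.normal(0, 1, size=9).tolist()
        data = self._data(a, b)
        _, p_raw = mc.feature_by_cluster_test(data, "F", 1)
        data2 = self._data(np.exp(a).tolist(), np.exp(b).tolist())
        _, p_exp = mc.feature_by_cluster_test(data2, "F", 1)
        assert p_raw == pytest.approx(p_exp, abs=1e-12)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(2, 1, size=30).tolist()
        b = rng.normal(0, 1, size=40).tolist()
        data = self._data(a, b)
        _, p = mc.feature_by_cluster_test(data, "F", 1)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)
        assert p < 0.001

    def test_empty_group_rejected(self):
        data = self._data([1, 2], [3, 4])
        with pytest.raises(ValueError):
            mc.feature_by_cluster_test(data, "F", 9)

    def test_bh_adjustment_table(self, clustered_benchmark):
        data, _ = clustered_benchmark
        table = mc.cluster_feature_table(data, ["SPEED", "AREA"])
        assert set(table.columns) == {"cluster", "feature", "statistic", "p", "p_adjusted"}
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
        assert len(table) == 2 * data.spots[mc.CLUSTER_COLUMN].dropna().nunique()
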