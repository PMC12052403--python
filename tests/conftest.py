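"""Shared fixtures: small hand-built datasets, a TrackMate XML fixture, and
one clustered benchmark shared by the dynamics/plot/acceptance tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import migroclust as mc


# ------------------------------------------------------------------- oracles


def ari_bruteforce(a, b) -> float:
    """Adjusted Rand index by explicit pair counting over all C(n,2) pairs."""
    a, b = list(a), list(b)
    n = len(a)
    n11 = na = nb = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        n11 += same_a and same_b
        na += same_a
        nb += same_b
    total = n * (n - 1) / 2
    expected = na * nb / total
    denom = 0.5 * (na + nb) - expected
    numer = n11 - expected
    if denom == 0:
        return 1.0 if numer == 0 else 0.0
    return numer / denom


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p-value by full enumeration of group assignments."""
    pooled = sorted(list(x) + list(y))
    n1, n2 = len(x), len(y)

    def u_of(group1_vals):
        # Mann-Whitney U of group 1 (count of (x, y) pairs with x > y, ties 0.5)
        rest = list(pooled)
        for v in group1_vals:
            rest.remove(v)
        u = 0.0
        for xv in group1_vals:
            for yv in rest:
                u += 1.0 if xv > yv else (0.5 if xv == yv else 0.0)
        return u

    u_obs = u_of(list(x))
    us = [u_of(list(c)) for c in itertools.combinations(pooled, n1)]
    n_total = len(us)
    p_le = sum(u <= u_obs for u in us) / n_total
    p_ge = sum(u >= u_obs for u in us) / n_total
    return min(1.0, 2 * min(p_le, p_ge))


# ------------------------------------------------------------------ fixtures


def make_small_migrdata() -> mc.MigrData:
    """3 spots in one track (frames 0,1,2), 2 edges, one ROI triangle."""
    spots = pd.DataFrame(
        {
            "spot_id": [1, 2, 3],
            "frame": [0, 1, 2],
            "t": [0.0, 10.0, 20.0],
            "x": [0.0, 1.0, 2.0],
            "y": [0.0, 0.5, 1.5],
            "track_id": [0.0, 0.0, 0.0],
            "visible": [True, True, True],
            "AREA": [50.0, 150.0, 150.0],
        }
    )
    edges = pd.DataFrame(
        {
            "source_spot_id": [1, 2],
            "target_spot_id": [2, 3],
            "track_id": [0, 0],
            "SPEED": [2.0, 4.0],
        }
    )
    tracks = pd.DataFrame({"track_id": [0], "filtered_in": [True], "NUMBER_SPOTS": [3.0]})
    roi = pd.DataFrame(
        {
            "spot_id": [1, 1, 1],
            "vertex_index": [0, 1, 2],
            "dx": [-1.0, 1.0, 0.0],
            "dy": [-1.0, -1.0, 1.0],
        }
    )
    return mc.MigrData(spots=spots, edges=edges, tracks=tracks, roi=roi)


MINIMAL_XML = """<?xml version="1.0" encoding="UTF-8"?>
<TrackMate version="7.11.1">
  <Model spatialunits="micron" timeunits="min">
    <AllSpots nspots="2">
      <SpotsInFrame frame="0">
        <Spot ID="10" name="ID10" VISIBILITY="1" FRAME="0" POSITION_X="1.0" POSITION_Y="2.0" POSITION_T="0.0" AREA="120.0"/>
      </SpotsInFrame>
      <SpotsInFrame frame="1">
        <Spot ID="11" name="ID11" VISIBILITY="1" FRAME="1" POSITION_X="1.5" POSITION_Y="2.5" POSITION_T="10.0" AREA="130.0"/>
      </SpotsInFrame>
    </AllSpots>
    <AllTracks>
      <Track name="Track_0" TRACK_ID="0" NUMBER_SPOTS="2">
        <Edge SPOT_SOURCE_ID="10" SPOT_TARGET_ID="11" SPEED="0.07"/>
      </Track>
    </AllTracks>
    <FilteredTracks>
      <TrackID TRACK_ID="0"/>
    </FilteredTracks>
  </Model>
  <Settings>
    <SpotFilterCollection/>
    <TrackFilterCollection/>
  </Settings>
</TrackMate>
"""


def make_filter_fixture() -> mc.MigrData:
    """10 spots in 2 tracks (5+5); only track 0 is filtered in.

    Track 0's areas are {50, 150, 150, 200, 250} so a spot filter AREA > 100
    retains 4 of its spots; the sub-fixture used by the filter-semantics
    checks restricts to the first three spots.
    """
    rows = []
    sid = 0
    for tid in range(2):
        for frame in range(5):
            rows.append(
                {
                    "spot_id": sid,
                    "frame": frame,
                    "t": frame * 10.0,
                    "x": float(sid),
                    "y": float(tid),
                    "track_id": float(tid),
                    "visible": True,
                    "AREA": [50.0, 150.0, 150.0, 200.0, 250.0][frame],
                }
            )
            sid += 1
    edges = []
    for tid in range(2):
        base = tid * 5
        for i in range(4):
            edges.append(
                {"source_spot_id": base + i, "target_spot_id": base + i + 1, "track_id": tid}
            )
    tracks = pd.DataFrame({"track_id": [0, 1], "filtered_in": [True, False]})
    return mc.MigrData(spots=pd.DataFrame(rows), edges=pd.DataFrame(edges), tracks=tracks)


def random_small_migrdata(seed: int) -> mc.MigrData:
    """Randomized small dataset for round-trip property checks."""
    rng = np.random.default_rng(seed)
    n_phen = int(rng.integers(1, 4))
    phenotypes = [
        mc.PhenotypeSpec(
            label=i + 1,
            feature_means={"AREA": 100.0 + 50 * i, "CIRCULARITY": 0.5 + 0.1 * i},
            feature_sds={"AREA": 10.0, "CIRCULARITY": 0.05},
            speed_mean=0.5 + 0.3 * i,
            speed_sd=0.1,
            turn_concentration=float(rng.uniform(0, 4)),
        )
        for i in range(n_phen)
    ]
    config = mc.SimConfig(
        n_tracks=int(rng.integers(1, 5)),
        track_length=int(rng.integers(2, 6)),
        frame_interval=float(rng.uniform(1, 20)),
        phenotypes=phenotypes,
        switch_prob=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**16)),
    )
    data, _ = mc.simulate(config)
    if rng.uniform() < 0.5:  # sparse annotation with missing entries
        ids = data.spots["spot_id"].tolist()
        some = {int(i): float(rng.normal()) for i in ids[: len(ids) // 2]}
        data = mc.attach_spot_annotation(data, "extra", some)
    return data


# ------------------------------------------------------- expensive fixtures


@pytest.fixture(scope="session")
def benchmark_data():
    data, truth = mc.default_benchmark(0)
    return mc.augment_spot_motility(data), truth


@pytest.fixture(scope="session")
def clustered_benchmark(benchmark_data):
    data, truth = benchmark_data
    config = mc.ICPConfig(n_runs=8)
    out = mc.cluster(data, mc.BENCHMARK_FEATURES, k_final=3, config=config, seed=1)
    return out, truth


@pytest.fixture(scope="session")
def blob_matrix():
    """Two 3-D Gaussian blobs separated by 6 sd per coordinate, standardized."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    truth = np.r_[np.zeros(100, dtype=int), np.ones(100, dtype=int)]
    return mc.FeatureMatrix(Xs, np.arange(200), ["a", "b", "c"]), truth
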