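"""Phenotype dynamics along tracks: stability, transitions, feature tests.

Clusters the benchmark data, then asks how persistent the phenotypes are
along each cell's trajectory and whether speed singles out one cluster.
"""

import migroclust as mc

data, _ = mc.default_benchmark(seed=0)
data = mc.augment_spot_motility(data)
clustered = mc.cluster(data, mc.BENCHMARK_FEATURES, k_final=3, config=mc.ICPConfig(n_runs=8), seed=1)

seqs = mc.track_sequences(clustered)
fraction, flags = mc.stability_fraction(seqs)
print(f"{len(seqs)} tracks; {fraction:.1%} show a stable pattern")
# a track is stable when strictly more than half of its spots share one cluster

counts, probabilities = mc.transition_matrix(seqs)
print("\nframe-to-frame cluster transition probabilities:")
print(probabilities.round(2))
# large diagonal entries = phenotypes persist; off-diagonal mass = switching

stat, p = mc.feature_by_cluster_test(clustered, "SPEED", cluster=1)
print(f"\nrank-sum test, SPEED in cluster 1 vs rest: U={stat:.0f}, p={p:.2e}")
table = mc.cluster_feature_table(clustered, ["SPEED", "AREA"])
print("\nper-cluster tests with Benjamini-Hochberg adjustment:")
print(table.round(4).to_string(index=False))
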