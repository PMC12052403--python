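"""Render all seven plot kinds for a clustered dataset.

Each plot function writes a figure file and returns the numeric table behind
it, so the printed output shows what the figures encode.
"""

from pathlib import Path

import migroclust as mc

data, _ = mc.default_benchmark(seed=0)
data = mc.augment_spot_motility(data)
clustered = mc.cluster(data, mc.BENCHMARK_FEATURES, k_final=3, config=mc.ICPConfig(n_runs=8), seed=1)

out = Path("figures")
out.mkdir(exist_ok=True)

mc.plot_umap(clustered, colour_by="cluster", path=str(out / "umap_clusters.png"))
mc.plot_umap(clustered, colour_by="SPEED", path=str(out / "umap_speed.png"))

fractions = mc.plot_pie(clustered, path=str(out / "pie.png"))
print("cluster proportions:")
print(fractions.round(3).to_string())

medians = mc.plot_heatmap(clustered, mc.BENCHMARK_FEATURES, path=str(out / "heatmap.png"))
print("\nper-cluster feature medians (heatmap values before row scaling):")
print(medians.round(2))

mc.plot_violin(clustered, "SPEED", path=str(out / "violin_speed.png"))
mc.plot_roi(clustered, spots_per_cluster=4, seed=0, path=str(out / "roi.png"))
mc.plot_rag(clustered, path=str(out / "rag.png"))
mc.plot_tracks(clustered, colour_by="cluster", path=str(out / "tracks.png"))

print(f"\nwrote 8 figures to {out}/")
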