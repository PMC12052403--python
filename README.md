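# migroclust

Phenotype clustering and track-dynamics analysis for cell-migration
tracking data.

Time-lapse microscopy of migrating cells is usually summarized at the track
level (mean speed, directionality), which hides the heterogeneity visible in
each cell's per-frame morphology and motility. `migroclust` works at the
level of *spots* — one segmented cell observation per frame — and clusters
them into phenotypes, so a single cell's trajectory becomes a sequence of
phenotype labels that can be analysed for stability and switching.

It is aimed at cell biologists and image analysts who already run a
segmentation-plus-tracking pipeline (e.g. TrackMate with a Cellpose
detector) and want to go beyond track statistics: which morphological states
exist in the population, which states move fast, and do cells stay in one
state or flip between states along a track.

## Method

The clustering core is an **iterative clustering projection (ICP)**
ensemble, a self-supervised scheme built around L1-regularized logistic
regression:

1. assign each of the N spots a uniformly random cluster label in 1..k;
2. draw a stratified sample of 30% of each cluster's spots and fit an
   L1-regularized multinomial logistic regression on it;
3. predict labels for all N spots, giving a proposed partition S′;
4. accept S ← S′ iff ARI(S′, S) exceeds the best value seen so far
   (starting from 0), where ARI is the adjusted Rand index

   ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − E),
   E = Σᵢ C(aᵢ,2) · Σⱼ C(bⱼ,2) / C(N,2);

5. repeat 2–4 until a run of non-improving iterations.

Because acceptance requires strictly increasing self-agreement, each run
converges to a partition that a sparse classifier can reproduce from a
subsample — clusters supported by discriminative features. L independent
runs yield N×k probability matrices that are concatenated and summarized by
PCA ("consensus PCA"); Ward hierarchical clustering on the PCA scores gives
the final partition at a user-chosen K, and UMAP a 2-D view. Downstream, a
track is called **stable** when strictly more than 50% of its labelled spots
share one cluster, and consecutive label pairs give an empirical phenotype
transition matrix.

A built-in generator produces synthetic experiments — persistent random
walks with per-phenotype morphology distributions, Markov phenotype
switching and known ground truth — for validation and benchmarking, and can
emit them as TrackMate-dialect XML.

## Worked example

```python
import numpy as np
import migroclust as mc

data, truth = mc.default_benchmark(seed=0)          # 600 spots, 60 tracks
data = mc.augment_spot_motility(data)               # edge SPEED/DCR onto spots
clustered = mc.cluster(data, mc.BENCHMARK_FEATURES, k_final=3,
                       config=mc.ICPConfig(n_runs=8), seed=1)

result = clustered.results["clustering"]
truth_labels = np.array([truth.spot_labels[s] for s in result.spot_ids])
print(mc.adjusted_rand_index(result.labels, truth_labels))
```

This prints a recovery ARI of `0.974`: almost every spot is grouped with its
generating phenotype (1.0 would be a perfect match). The track-level view
(`examples/02_track_dynamics.py`) then reports

```
60 tracks; 93.3% show a stable pattern

frame-to-frame cluster transition probabilities:
      1     2     3
1  0.95  0.03  0.02
2  0.03  0.94  0.03
3  0.02  0.03  0.95
```

— phenotypes persist along tracks (strong diagonal), with occasional
switches matching the generator's 5% per-frame switching rate, and a
rank-sum test singles out the fast cluster by speed (p ≪ 0.001).

The `examples/` directory has one short script per capability: simulate and
cluster, track dynamics, TrackMate XML interchange, and the seven plot
kinds (UMAP, pie, heatmap, violin, ROI outlines, rag plot, track overview).
The same workflow is scriptable from a shell via the `migroclust` command
(`import`, `simulate`, `cluster`, `dynamics`, `plot`).

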