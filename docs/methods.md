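# Methods

## Data model

A migration experiment is held in a `MigrData` with three tables: **spots**
(one segmented cell observation per frame: position, acquisition time, an
open set of numeric morphology/intensity features, an optional outline
polygon stored as offsets from the spot centre), **edges** (links between
the same cell's spots in consecutive frames, carrying motility features such
as SPEED and DIRECTIONAL_CHANGE_RATE) and **tracks** (whole trajectories
with summary features). Feature sets are deliberately open maps rather than
fixed schemas: tracking software emits different feature lists depending on
version and detector, and unknown features are preserved verbatim. Missing
values are plain NaN. Referential integrity (edge endpoints exist, track ids
resolve, outlines have ≥ 3 vertices, per-track spot counts match) is checked
on construction and exposed as a validator that returns an issue list.

Archives are zip files of per-table CSVs plus JSON sidecars for metadata,
recorded filters and analysis results — language-portable and diffable, with
no binary pickles. Equality between two `MigrData` objects compares tables
as keyed record sets (row order is not semantic), treats NaN as equal to
NaN, and ignores the `source_file` provenance entry, which describes the
physical file rather than the data.

TrackMate-dialect XML (v7 attribute conventions: `POSITION_X/Y/T`, 0-based
`FRAME`, ROI offsets in the Spot element text) is read and written such that
import ∘ export is the identity. `Infinity`/`NaN` tokens and non-numeric
attributes map to missing values (the latter with a warning). Spots keep
their track assignment via edge membership; spots touched by no edge remain
unassigned. Applying the recorded filters keeps a spot iff it passes every
spot filter *and* belongs to a track listed in `FilteredTracks`; the
operation is idempotent and never grows any table. Because speed and
directional change rate live on edges but clustering needs them per spot,
`augment_spot_motility` projects them onto spots; the default policy is the
mean over a spot's incident edges (`incoming`/`outgoing` are selectable —
the projection is genuinely a modelling choice, since a spot sits between
two measurements of its cell's motion).

## Clustering

Selected features are assembled into an N×F matrix; rows with missing
values are dropped (default) or median-imputed, then each column is
z-scored with the sample standard deviation. Zero-variance columns are
removed with a warning. NA handling precedes standardization so imputation
cannot shift the scale.

One ICP run: random labels in 1..k → stratified 30% subsample per cluster
(ceil, at least 1, without replacement) → L1-regularized multinomial
logistic regression (saga solver, inverse regularization C = 0.3) → predict
all spots → accept the prediction iff its adjusted Rand index to the current
labels exceeds the best ARI so far (initialized to 0). The run stops after 5
consecutive non-improving iterations or 200 iterations. The returned
probability matrix comes from the last accepted model; classes absent from a
training sample contribute zero-probability columns so rows always sum
to 1. A constant (single-label) prediction can never be accepted — its ARI
to any partition is ≤ 0 — and counts as a stalled iteration; a run in which
nothing is ever accepted is restarted with a shifted seed up to 3 times and
then returns its degenerate soft assignment rather than raising, so
pathological inputs (e.g. identical rows) terminate cleanly.

The adjusted Rand index is computed from the contingency table by the
pair-counting formula; when the chance-correction denominator vanishes the
index is defined as 1 if the numerator also vanishes (the limit of perfect
agreement, e.g. two all-singleton partitions), else 0.

Defaults follow the lineage of the method: ensemble size L = 50, per-run
k = 15, consensus PCA dimension p = 50 (capped at L·k and N−1), C = 0.3.
The per-run k is intentionally larger than the expected number of
phenotypes: individual runs over-segment, and the ensemble's concatenated
N×(L·k) probability matrix — column-centered, then reduced by exact-solver
PCA — carries the consensus geometry. Ward linkage on the PCA scores gives
a dendrogram that is cut at a user-chosen K_final (no automatic K
selection; the linkage is stored so users can re-cut without re-running
ICP). Final labels are re-indexed 1..K by decreasing cluster size, ties
broken by the smallest original label. UMAP (seeded, n_neighbors capped at
N−1) provides a 2-D view and refuses N < 10, where a direct PCA scatter is
more honest. Every stage takes explicit integer seeds and no global random
state is touched; ensembles use seeds base..base+L−1 so parallel execution
equals sequential.

A note on single runs: under the monotone-acceptance rule the first accepted
model is fitted to essentially random labels, so an individual run can lock
onto an arbitrary self-consistent split (or never take off) — recovery of
true structure is a property of the *ensemble consensus*, not of single
runs. On two 6-sd-separated Gaussian blobs the consensus pipeline recovers
the generating labels exactly while individual k=2 runs do so only for some
seeds.

## Track dynamics

Cluster labels attached to spots turn each track into a frame-ordered label
sequence; unlabelled spots (e.g. dropped by NA handling) stay in the
sequence as gaps. A track is **stable** iff strictly more than a threshold
fraction (default 50%) of its labelled spots share one label — strict, so a
50/50 two-cluster track is unstable. Transition counts aggregate
consecutive labelled pairs; a missing label breaks the chain (no pair is
counted across it) rather than acting as a state, a conservative choice
that cannot invent transitions. The row-normalized matrix leaves all-zero
rows at zero. Tracks are ordered for linearized display by a track feature
(default mean directional change rate), ascending, missing last, ties by
track id. The per-cluster feature test is a two-sided Wilcoxon rank-sum
(Mann–Whitney) test of one cluster against all other labelled spots, exact
when both groups have ≤ 10 observations and a continuity-corrected normal
approximation otherwise; the all-clusters × all-features table reports
Benjamini–Hochberg adjusted p-values alongside raw ones, with no correction
applied to single tests.

## Synthetic data

The generator emulates what a segmentation-plus-tracking pipeline produces,
with ground truth attached. Each track is a persistent random walk: per
frame the heading turns by a wrapped-normal angle with per-phenotype
concentration κ (sd = 1/√κ; κ = 0 means uniform turning) and the step
length is Normal(speed·Δt, speed_sd·Δt) truncated at 0 (truncation rather
than reflection; bias is negligible at default parameters). Morphology
features are drawn independently per frame from the phenotype's normal
distributions — the simplest model under which per-timepoint clustering is
well-posed; temporal autocorrelation of morphology is deliberately not
modelled, so tests passing here say nothing about autocorrelated real
morphology. Phenotypes switch with per-step probability ε, the destination
drawn from a zero-diagonal row-stochastic matrix (or uniformly over the
other phenotypes), making the truth labels a Markov chain with per-frame
matrix (1−ε)I + εM — the analytic reference for transition-recovery checks.
Edges carry SPEED = step/Δt and DIRECTIONAL_CHANGE_RATE = |turn|/Δt,
assigned to the edge following the turn; the first edge of a track carries
0 since no turn precedes the first step. Track summaries (NUMBER_SPOTS,
TRACK_DURATION, TRACK_MEAN_SPEED, MEAN_DIRECTIONAL_CHANGE_RATE) are
computed from the generated spots and edges. Outlines are 12-vertex
ellipses from the spot's ellipse axes at a random orientation; when axes are
not specified they are derived from AREA and aspect ratio.

The standard benchmark has 3 phenotypes whose means differ by 4 sd on four
morphology features (area, circularity, ellipse aspect ratio, radius) with
distinct speed/turning regimes — a spread slow explorative phenotype, an
elongated fast persistent one, and a small round erratically turning one —
over 60 tracks × 10 frames (N = 600) with ε = 0.05. These sizes keep a full
pipeline run in the tens of seconds on one CPU while leaving each phenotype
~200 spots.

Real data differ from the generator in ways that bound what the benchmarks
show: real morphology is temporally autocorrelated, segmentation errors
produce outliers and implausible outlines, intensity features covary with
morphology, and gaps/splits occur in tracks. Passing the recovery benchmark
demonstrates the pipeline's correctness and its behaviour under honest
noise, not performance on any particular microscope dataset.

## Numerical and testing notes

- Recovery benchmarks use an ensemble of L = 8 runs (default 50) and five
  generator seeds with the median reported; measured medians are ~0.97.
- The benchmark clusters on the four morphology features plus speed.
  Per-spot directional change rate is excluded from that feature list: for
  weakly persistent phenotypes |turn|/Δt is close to uniform over its whole
  range, so the feature's within-phenotype spread swamps its
  between-phenotype signal, and a small ensemble will slice along the
  resulting noise dimension and mix the slow phenotypes. The feature is
  still generated, round-tripped and used at the track level (ordering by
  mean directional change rate), where averaging restores its signal.
- XML numeric round-trips use 17-significant-digit formatting (exact for
  doubles); equality tolerances elsewhere are 1e-9.
- Probability rows are checked to sum to 1 within 1e-8; acceptance traces
  are strictly increasing by construction.
- Figures are written to files and every plot function returns its
  underlying numeric table (medians, proportions, orderings), so tests
  assert numbers, never pixels; all plot sampling is seeded.
- The rag plot's time axis is the frame index, not physical time, so gap
  frames render as blanks; the track overview uses image-style y-down axes
  by default with a flag to flip.
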