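# Methods

## Problem setting

`aggloseg` segments 2D images and isotropic 3D volumes (the motivating case
is electron-microscopy volumes of neural tissue) by hierarchical
agglomeration of watershed superpixels.  The inputs are an integer
superpixel map, one or more real-valued pixel cue maps in [0, 1] (a
boundary-probability map first, optionally cytoplasm/texture channels), and
— for training — a gold-standard segmentation of the same volume.  Cue
computation (membrane detectors, texture filters) is upstream of this
package: cues are inputs, never computed here.

## Region adjacency graph

The RAG holds one node per current region and an edge wherever two regions
touch under face connectivity (4-connectivity in 2D, 6 in 3D; diagonal
contact does not create an edge).  Every node caches, per cue channel, a
fixed-range histogram over [0, 1] (default 25 bins) and the raw power sums
Σv..Σv⁴, from which the mean and central moments 2–4 are derived on demand;
merging two regions is then plain addition, and the cached statistics equal
a from-scratch recomputation to well below the 1e-9 tolerance asserted in
the tests.  Edges store the set of boundary pixel indices — by default the
two-sided ("thick") boundary: pixels of either region with a face neighbour
in the other.  For superpixel maps that keep 0-labelled watershed lines,
`boundary_mode="ridge"` instead samples the 0-pixels adjacent to both
regions (and also connects regions that touch only through such a line);
an edge with no ridge pixels falls back to its direct-contact pixels so
every edge has a non-empty boundary.  Edge statistics are computed lazily
from the pixel set and cached; merging unions the sets, so a pixel adjacent
to both merge partners is counted once and edge statistics stay exact.
The surviving node of a merge keeps the smaller id, which makes node ids a
subset of the original superpixel ids and merge histories replayable.

## Features

The merge priority decomposes into a feature map and a classifier.  Per cue
channel, the feature vector of a candidate merge (u, v) concatenates, for
the edge boundary and for each region: approximate quantiles of the
histogram (linear interpolation of cumulative bin mass; 3 quantiles =
quartiles, 9 = deciles), the pixel count, the mean, and the unnormalized
central moments 2–4; plus the absolute differences of the regions'
means/moments and the Jensen–Shannon divergence between their normalized
histograms (log base 2, so JSD ∈ [0, 1] bits).  The two region blocks are
ordered smaller-region-first with ties broken by node id, making the
vector exactly symmetric under swapping u and v.  In 2D an optional
mid-level block adds three relative orientation angles in [0, π/2]
(principal axes from the per-region second-moment matrices, plus each axis
against the centroid-connecting segment; degenerate comparisons return the
π/4 midpoint) and three convexity ratios (region area over convex-hull
area for each region and their union, pixels counted as unit squares so a
solid rectangle scores exactly 1).  Second-moment accumulators and hull
vertices are maintained only when mid-level features are enabled, to bound
memory in 3D.

## Best agglomeration and training labels

The best agglomeration A* assigns every superpixel to the gold segment
with which it shares the most overlap (ties to the smallest gold id;
superpixels overlapping only unlabelled gold go to a dedicated group with
a warning).  By default each group is then refined into its connected
components in the superpixel adjacency graph.  The refinement exists
because the training epoch merges only edges whose two regions lie in one
group: a group that is disconnected at superpixel resolution could never
be assembled by such merges, and the epoch's termination condition — the
graph grouping exactly equals A* — would be unreachable.  Refined A* is
precisely the best segmentation *achievable by adjacency-constrained pure
merging*, which is the object the training loop needs.  The literal
assignment is available with `split_disconnected=False`.

Merge labels: +1 ("should merge") when both regions lie in one reference
group, −1 ("don't merge") when each lies wholly in a different group, 0
("don't know") when a region mixes groups.  Labels are computed against A*
by default, which guarantees a 0-free training set during guided epochs.
`label_source="gold"` implements the literal definition against the gold
standard; 0-labelled examples are then recorded in the training-set
provenance but excluded from fitting, and a +1 edge whose endpoints fall
in different achievable groups is refused to preserve termination.

## Training protocols

*Flat learning* labels every edge of the initial graph and fits the
classifier once; it sees only superpixel-scale statistics.

*Active agglomerative learning* repeats, for a configurable number of
epochs (default 5), on a freshly rebuilt graph: pop the current policy's
lowest-scoring edge; record its pop-time features and label; merge only on
+1; stop exactly when the grouping equals A*.  A refused edge is not
re-queued until one of its endpoints changes (lazy invalidation with
per-node version stamps).  The data from all epochs, plus the flat
bootstrap set, are concatenated and a new policy is fitted after each
epoch.  The initial policy is the flat classifier by default
(`init_policy` also accepts `mean` and `random`).

*LASH* is the comparison protocol: merges always proceed to completion,
each merge is labelled by the sign of the Rand-index change it causes
(computed incrementally from per-region gold-overlap counts, gold-0 pixels
excluded; zero changes are dropped), and only the final epoch's data feeds
the final fit.

## Classifier and score convention

A policy scores an edge in [0, 1] with *low = merge first*; the score is
the estimated probability that the edge is a true boundary, i.e.
1 − P(merge).  This makes the mean-boundary baseline (score = mean
boundary-cue value over the edge), learned policies, and the canonical 0.5
operating point directly comparable, and agglomeration merges minimum-score
edges while the score is strictly below the threshold (so threshold 0 is a
no-op).

The default classifier is a seeded 100-tree random forest
(`min_samples_leaf=5`, single-threaded for reproducibility) wrapped in
sigmoid (Platt) calibration fitted by 3-fold cross-validation.  The
calibration wrapper exists because the probability *scale* matters here,
not just the ranking: the active protocol generates a training set heavily
tilted towards +1 (every spanning merge contributes a positive example),
and raw vote fractions inherit that prior, shifting the useful operating
point away from 0.5 for every learned policy.  Calibration is applied
identically to flat and active policies; the difference that remains at
the 0.5 operating point is the one the method is about — whether the
training feature distribution matches the distribution encountered during
a test agglomeration.  Any estimator exposing `fit`/`predict_proba` can be
substituted via `classifier_factory`; the fitted classifier, feature
schema and provenance summary are stored together in the model file.

## Evaluation framework

All metrics are computed from the contingency table of candidate against
reference.  Reference label 0 is excluded by default (unlabelled gold must
not count as error); candidate 0 is a real segment unless excluded
explicitly.  Entropies are in bits.  The variation of information
VI = H(S|U) + H(U|S) splits into the false-split ("over", H(S|U)) and
false-merge ("under", H(U|S)) terms; the split-VI curve traces (under,
over) across thresholds, and the per-segment breakdown lists (segment,
mass p, conditional entropy H) sorted by contribution p·H.  Rand index and
the Hubert–Arabie adjusted Rand index use exact pair counting.
`adjusted_rand_error` is the pair-counting Rand F-score error
(1 − harmonic mean of pair precision and recall), the form used to rank EM
segmentation challenges; it is 0 for identical partitions including the
all-singleton and single-segment edge cases.  Covering is the
size-weighted mean best IoU, reported in both directions because the
one-directional convention differs between benchmarks.  ODS picks one
threshold optimizing the mean score across images (ties to the smallest
threshold); OIS averages per-image optima.

Threshold sweeps can either re-run agglomeration per threshold or cut a
single saved merge history; both are provided.  A history cut replays
recorded merges with score below the threshold in recorded order.  For
histories produced with `monotone=True` (scores clamped to the running
maximum) a cut is identical to a fresh run at that threshold; raw
histories may differ slightly where re-scored edges dropped below an
earlier stopping point.

## Synthetic phantoms

The generator produces the three inputs end-to-end so every experiment is
self-contained.  Geometry: `voronoi` phantoms partition the image into
nearest-seed cells; `tubes` phantoms (3D) are elongated processes spanning
z, started on a jittered grid and wandering smoothly with sub-grid
amplitude so trajectories never cross and every region stays connected.
A named pinch phantom (a dumbbell joined by a one-voxel neck) probes the
neck failure mode where sum-based boundary features carry least evidence.

The boundary cue is the blurred (σ = 1) boundary indicator modulated,
before blurring, by a smooth random strength field (Gaussian noise
smoothed at correlation length 8 px, rescaled to the range (0.1, 1.1) and
clipped to [0, 1]), plus pixel noise of sd 0.1.  The strength field is the
deliberate realism: real membrane detectors fade in and out along a
boundary, and those weak stretches are what make plain mean-boundary
agglomeration err.  The texture cue draws one intensity level per segment
from the narrow range (0.35, 0.65) and adds strong pixel noise (sd 0.25):
region identity is then ambiguous at superpixel size but sharply estimated
once regions grow, so the informativeness of region statistics is
scale-dependent — evidence an agglomerative training loop can exploit and
flat training cannot.  Superpixels are watershed basins of the smoothed
cue seeded at local minima at least 3 px apart, giving roughly 250
superpixels for 12 segments on the default 128×128 phantom — several merge
generations between superpixel and segment scale.

What the phantoms do not emulate: real EM texture, anisotropy, imaging
artefacts, cue detectors with spatially correlated *systematic* errors, or
gold standards with unlabelled regions.  Passing the synthetic suite
demonstrates the correctness of the machinery and the presence of the
scale-calibration phenomenon under controlled conditions, not performance
on any real dataset.

## Study conditions used by the test suite

* Deterministic properties (graph/statistic exactness, queue-vs-oracle
  equivalence, metric axioms) run on random volumes up to 12×12 with up to
  9 superpixels, 100–200 cases, tolerance 1e-9.
* Training-loop contracts and self-consistency run on 64×64 phantoms with
  6 segments, visible boundaries (strength range (0.7, 1.1), noise 0.05)
  and mild texture noise (0.1), seeds 0–2: a learnable setting, since the
  claim under test is that the loop terminates exactly at A* and that the
  trained policy reproduces it at threshold 0.5.
* The calibration phenomenon runs at the default phantom conditions
  (128×128, 12 segments, graded boundaries, ambiguous texture), train
  seeds 0–4 paired with test seeds 100–104, 5 training epochs, thresholds
  0.05–0.95 in steps of 0.05.  These sizes keep the full suite within a
  few minutes on one CPU while leaving roughly an order of magnitude
  between superpixel and segment scale.

## Known limitations

* The active loop trains only on trajectories that never leave the pure
  grouping, so features of impure regions formed at test time are
  extrapolated; this is inherent to the protocol (LASH makes the opposite
  trade-off).
* Merge decisions are greedy and local; no global consistency pass.
* The per-edge boundary pixel sets make memory proportional to total
  boundary area, which is acceptable at desk scale but would need
  summarized storage for teravoxel volumes.
* `cut_history` on non-monotone histories is a dendrogram cut, not a
  re-run; the two coincide only under monotone score clamping.
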