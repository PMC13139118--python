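# Methods

`neutrack` implements tracking by detection for highly motile fluorescent
cells (its motivating case is neutrophils recruited to a wound in
zebrafish larvae): cells are segmented in every frame, candidate linkages
between adjacent frames are scored by predicted-mask overlap, and
trajectories are linked globally by an extended Viterbi algorithm that
handles appearance, disappearance, merging and splitting. This note
records the model, the numerical choices, and what the built-in synthetic
data does and does not establish.

## Synthetic time-lapse generator

The generator emulates the acquisition regime the pipeline targets:
512×512 frames, 120 frames per sequence at 1-minute intervals, roughly
10–40 cells per frame. Those are the `SimConfig` defaults.

**Appearance model.** Cells are rendered as smooth-edged discs: the
radial intensity profile is `peak · ½(1 − erf((d − r) / (√2·σ_e)))` with
edge width σ_e = 0.5 px. The ground-truth mask cuts the profile at 20 %
of peak. A disc with a Gaussian-smoothed edge (rather than a Gaussian
radial profile) is used deliberately: with a pure Gaussian profile, the
area enclosed by an intensity threshold grows like `ln(1/t)`, so a
segmenter thresholding at t = 0.1 would always overshoot a 20 %-of-peak
mask by the fixed factor ln10/ln5 ≈ 1.43 and could never exceed IoU ≈
0.70 against it. With the erf edge, the reference segmenter at t = 0.1
reaches IoU > 0.9 on noise-free defaults, which is the regime the
downstream stages assume. Irregular neutrophil morphology is only
approximated (an optional eccentricity stretches blobs along the
heading); texture is not modelled.

**Motion model.** A persistent random walk: each frame the heading is the
normalised sum `persistence · previous + (1 − persistence) · random unit
vector`, and the cell advances by its per-cell speed (drawn once from
`speed_mean · U(0.5, 1.5)`). Defaults `speed_mean = 2 px/frame`,
`persistence = 0.7` were chosen once as a realistic regime for
wound-recruited neutrophils at ≈1 µm/px and 1 min/frame (2 µm/min mean
path speed, directionally persistent over a few minutes); they are not
fitted to any dataset. Cells reflect at the image border; with
`min_separation` set, a step that would violate the pairwise distance is
cancelled and the heading reversed, which is how the `clean_separated`
regime guarantees unambiguous geometry.

**Events.** Cells disappear stochastically (`p_disappear`/frame) and
appear at a random border moving inwards (`p_appear`/frame). Scripted
merge/split events override the walk: during the merged interval the
second track sits at a fixed small offset from the anchor so both blobs
form one connected labelled region that both ground-truth tracks
reference; at the split the second track is displaced clear of the
anchor and resumes its own displacements. Identical config + seed gives
bit-identical output (one `numpy.random.default_rng(seed)` drives
everything).

## Preprocessing

Maximum intensity projection collapses a z-stack per-pixel; the per-frame
chain is percentile contrast stretch (defaults 1 / 99.8), median filter
(radius 1), Gaussian blur (σ = 1), in that order. Both filters use
scipy's `reflect` boundary (edge sample duplicated) so outputs are
bit-reproducible. The synthetic frames are clean, so the pipeline applies
the chain only on request.

## Reference segmentation and its evaluation

The reference segmenter min–max normalises a frame, thresholds at
t = 0.1 (the default balances foreground area against missed small
cells), labels 8-connected components and drops components under 5 px.
It is a deterministic classical stand-in at the interface where any
instance segmenter could be plugged in.

Segmentation quality: semantic IoU on the union foreground; object-level
F1 = 2·TP / (2·TP + FP + FN) with objects matched by *mutually maximal
pixel overlap* (a (truth, pred) pair counts as a true positive iff each
is the other's largest-overlap partner — this rule is order-independent
and makes the FP/FN/merge/split counts well defined); a prediction
overlapping ≥2 truth objects counts one under-segmentation, a truth
object overlapped by ≥2 predictions one over-segmentation.

## Scoring

For each cell at frame t the proxy predictor dilates its pixel set by
`search_radius` (default 10 px — above the largest per-frame displacement
the simulator produces by default); the dilated support is intersected
with the frame-t+1 labels. Raw overlaps are normalised by the prediction
area (default; alternatives: target area, union), giving entries in
[0, 1]. An adapter accepts externally supplied per-cell prediction masks
(e.g. from a learned motion model); when such a prediction contains
several blobs, the connected component with the highest mean raw-frame
intensity is kept.

The proxy predictor is purely spatial: it carries no motion direction.
That is sufficient for well-separated cells but cannot, even in
principle, preserve identities through a merge — the score rows out of a
shared detection are identical for every track occupying it. This is
exactly why the scoring stage is an interface: a learned, motion-aware
scorer slots in above the linkage layer unchanged.

## Linkage

All four linkers consume the same score-matrix chain.

**Greedy.** Frame-synchronous argmax; each detection can be passed by one
trajectory only. A track whose best candidate is already claimed ends
(`ended_no_available_cell`); unclaimed detections seed new trajectories.
The rule is strict argmax — no fallback to the second-best candidate.

**Hungarian.** Per frame pair a maximum-score one-to-one assignment
(`scipy.optimize.linear_sum_assignment` on the negated scores);
assignments scoring 0 are dead ends, those under `end_threshold` end the
track as disappeared; unassigned next-frame cells seed new tracks.

**Basic Viterbi.** Per seed, forward dynamic programming over the whole
chain (node value = best accumulated product reaching it, computed in log
space) and backward retrieval of the argmax path, preferring the longest
reachable path, then the highest product; ties break toward the lower
cell label. There are no occupancy constraints, so after a merge the
per-seed optima collapse onto shared nodes. A truncation post-processing
cuts a trajectory at the first step whose score falls below the previous
step's, once the trajectory has entered a shared node; detections
orphaned by the cut are re-seeded. The truncation rule is an
interpretation of a loosely specified post-processing step and is
isolated in one function (`truncate_collapsed`).

**Extended Viterbi.** Tracks are routed sequentially — first-frame cells
in ascending label order, then appearing cells in frame order — each by
the same forward/backward machinery, but consulting an occupancy map. A
transition into a node occupied by other trajectories is allowed only if

* Condition 1: the routing track's accumulated product at that node is at
  least the discounted merge threshold, or
* Condition 2: every occupant's accumulated product at that node is below
  its own discounted threshold.

The threshold is discounted geometrically,
`DiscountThreshold = T_merge^(frame_number − 1)` with `frame_number`
counted from the track's birth frame (accumulated scores are products of
per-step probabilities, so a fixed threshold would become unreachable
within a few frames). Defaults `T_merge = 0.875`, `T_truncated = 0.001`.
A step scoring below `T_truncated` is unusable; a track whose best
remaining transition is positive but below the floor terminates as
`truncated_disappeared` (out of field of view), distinct from
`ended_zero_scores` and `ended_no_available_cell` so the three end
conditions are discriminable. After routing, every uncovered detection
seeds a new trajectory.

Merging is node sharing under the conditions; splitting happens at the
first layer where a merged track's conditions fail or its own optimum
diverges — in practice the discounting drives this: merged-interval step
scores below `T_merge` erode a track's slack against the discount line
until it is excluded from the contested continuation and must take its
own. A later track entering a node via Condition 2 with a strictly
better accumulated product (factor `reroute_factor`, default 1 — strictly
greater wins) evicts the weak occupant, which is truncated at the
contested layer and re-routed from its previous node; a single sweep, no
cascading, so termination is guaranteed. Seed nodes are never evicted.
All shared-node decisions are logged (`TrackingResult.merge_log`) with
the condition that admitted them.

**The crossing-cells fixture.** `two_cells_cross_merge_split` scripts two
cells that approach, share one detection for two frames, and separate
continuing in their original directions. Because the proximity scorer is
directionless (above), the fixture ships engineered score matrices that
emulate a motion-aware scorer: the large left-to-right cell carries step
confidence 0.97 (entry 0.93), the small right-to-left cell 0.91, the
merged step 0.87, and the exits score 0.75 (large cell's side) and 0.62.
Hand-checking the arithmetic against the discount line (0.875^(layer−1)):
both tracks clear the discounted threshold when entering the shared node
(0.774 ≥ 0.766 and free routing respectively), and at the split layer the
second track's candidate at the contested exit (0.49) is below the
discount (0.513) while the occupant's product (0.57) is above it — both
conditions fail, so the second track diverges to its own side. Greedy
strands the second track at the merge; basic Viterbi collapses both
tracks onto the same exit. The fixture therefore isolates the linkage
algorithm's contribution, not the scorer's.

## Tracking evaluation

Ground truth and predictions share one table schema (track_id, frame, x,
y). A predicted node *identifies* the nearest ground-truth object within
a matching radius (default 10 px); each track is matched to the object it
identifies in the majority of its frames (ties toward the lower id).
Track purity averages, over tracks, the fraction of a track's frames
identifying its match; object purity averages, over objects, the fraction
of an object's frames identified by a track matched to it. FIT counts
(frame, object) identifications by a wrongly-matched track, FIO counts
(frame, track) events where a track identifies a non-matched object; both
are normalised per frame per cell (÷ n_frames × mean ground-truth cells
per frame). The frame-level identification rule and the majority matching
are a minimal completion of the purity-metric family — absolute FIT/FIO
values depend on the matching radius, so only comparisons under the same
rule are meaningful.

Cross-method comparison: Kruskal–Wallis omnibus per metric; if
significant, Dunn's pairwise z-tests (rank sums with tie correction —
implemented here, as no post-hoc package is a dependency) with
Benjamini–Hochberg adjustment.

## Migration statistics

Net displacement = |last − first| (µm, via `pixel_size`); total distance
= Σ step lengths; meandering index = net / total (0, flagged, for a
degenerate zero-length path); mean speed = total / (n_steps ×
frame_interval) — travel time uses the number of steps, not frames.
A cell is *distant* when its average per-step displacement exceeds
2.4 µm. "Average net displacement between frames" is ambiguous between
mean step length and net displacement ÷ n_steps; both are implemented
(`distant_mode="step" | "per_frame"`), default mean step length, which is
the quantity that grows with sustained travel. Group comparison is an
independent-samples t-test with means ± SD.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use scaled problem sizes
chosen as the smallest that exercise each behaviour: 200 random chains of
≤5 frames × ≤4 cells for the exhaustive-enumeration oracle (the oracle is
exponential by design), a 20-cell/60-frame noise-free simulation for
parameter recovery, a 2-cell/120-frame sequence for the frame-counting
identity, and the ≤10-frame scripted fixtures. Every stochastic source
takes a seed; the simulator is bit-reproducible per (config, seed).

## Known limitations

* The proximity scorer cannot disambiguate identities through merges
  (by construction); motion-aware scores must come from outside.
* The simulator's blobs are far simpler than neutrophil morphology;
  passing tests establish the correctness of the pipeline's algorithms
  under known geometry, not segmentation or tracking accuracy on real
  recordings.
* Merge rendering fuses blobs pairwise at a fixed offset; partial
  occlusions and true 3D overlap are not modelled, and z-stacks are only
  supported through projection.
* The extended Viterbi's routing order matters under heavy contention;
  the single reroute sweep mitigates but does not eliminate order
  dependence.
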