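# Methods

## Setting and model

The package addresses re-identification of individual animals in a single
short video.  A multiple-object tracker (or a manual annotator) supplies a
set *Z* of *N* bounding boxes, each with a frame index, box coordinates and a
track label; a feature extractor supplies an appearance vector per box.  The
task is to assign each box one of approximately *K* identity labels, where
*K* is assumed known (a keeper knows how many animals are in the pen).

Two sources of pairwise information come free with video and are treated as
hard constraints:

* boxes within one track are the same animal (must-link; tracks are trusted
  and never split);
* boxes within one frame are different animals, so two tracks that co-occur
  in any frame are cannot-linked (CL) and may never end up in one cluster.

## Classifier-based clustering

CBC merges tracks down to *K* identities.  Each iteration trains a classifier
on the feature vectors using the current track labels as classes, reclassifies
the same data (resubstitution), and forms the confusion matrix.  The diagonal
is zeroed, CL pairs are zeroed symmetrically, and each row is scaled to sum to
one, turning entry *(p, q)* into the proportion of track *p*'s members that
look like track *q*.  The largest entry nominates a merge: the row track is
relabelled to the column track.  The loop stops at *K* surviving tracks or
when the matrix is all zero (every remaining merge is blocked or unsupported).
After a merge the surviving track's frame set is the union of both tracks'
frames, and CL constraints are recomputed from those unions each iteration, so
constraint respect is invariant under merging.  Output labels are always a
coarsening of the input tracks; with clean (frame-pure) input tracks no output
cluster can contain two same-frame boxes.

Numerical/tie-break choices (the procedure's only free details):

* largest-entry ties resolve to the lowest row label, then lowest column
  label (rows and columns are kept in sorted label order, so the first
  row-major maximum is that entry);
* rows whose masked confusion counts are all zero stay all-zero rather than
  being renormalized;
* merge direction is row-into-column;
* only the row-scaled matrix is offered — scaling is what makes a small track
  absorbed by a large one visible, and an unscaled variant measurably
  degrades merge ordering.

The classifier is pluggable behind a fit/predict contract that must accept
single-member classes, because fragmented videos produce singleton tracks in
bulk.  The default is **nearest-centroid**: linear-time training inside the
merge loop, purely appearance-driven, robust to singletons.  One known
consequence of resubstitution with nearest-centroid: a singleton track's
point is at distance zero from its own centroid, so its row is always zero
and it can only be absorbed through its column (another track's members
classifying as it).  Outlier singletons — e.g. boxes dominated by an
occluding animal — may therefore survive to the end, which is why runs on
heavily occluded scenes can stop above *K* with a residue of tiny clusters.
k-NN with k=1 is degenerate under resubstitution (every point is its own
nearest neighbour, the confusion matrix is diagonal) and is excluded from
the oracle tests; the k-NN option defaults to k=3.

*K* is treated as an exact stopping target; when the input already has at
most *K* tracks the labels are returned unchanged.

## Appearance descriptor

Each box is clamped to the image, divided into a 3×3 grid with cell
boundaries at ⌊i·w/3⌋ and ⌊i·h/3⌋ (cells differ by at most one pixel and
partition the box), and each cell contributes mean and standard deviation of
each RGB plane: 54 values on the raw 0–255 scale.  The standard deviation is
the population form — the descriptor describes the pixels it sees, it does
not estimate anything.  The minimum clamped box is 3×3 pixels.  Features are
kept raw for CBC (nearest-centroid on intensity units); distance-based
baselines z-score them per dataset, which matches a DBSCAN radius grid of
order 1.  Whether to standardize is a flag, not a baked-in assumption.

## Track generation (BASIC)

Between every pair of consecutive frames the IoU of all box pairs is
computed from continuous areas, pairs under the threshold (default 0.7) are
inadmissible, and the Hungarian algorithm selects the one-to-one assignment
maximizing total IoU — relevant exactly when two boxes compete for the same
predecessor.  Ties between equal-total assignments prefer the lower previous
index, then the lower current index, via an epsilon bonus (1e-9 scale) that
cannot override a genuine IoU difference at realistic precision.  A box
unmatched for even one frame starts a new track; there is no association
across frame gaps.  The alternative greedy per-box matching was rejected in
favour of the assignment optimum, which is the standard Hungarian reading of
"best fit".

## Evaluation metrics

ARI (Hubert–Arabie), NMI normalized by the arithmetic mean of the label
entropies, counting accuracy (majority many-to-one cluster→class mapping) and
Hungarian accuracy (optimal one-to-one mapping on the contingency table,
unmatched clusters scoring zero).  The arithmetic-mean NMI variant and the
majority-mapping ACC definition are the ones consistent with the analytic
anchor values the battery reproduces (an all-singleton labeling scores
ACC = 1 exactly, HACC = #classes/N).  ARI's degenerate denominator (both
partitions trivial with identical pair structure) returns 1 for identical
partitions and 0 otherwise.  The sanity battery scores four constructed
labelings — random labels, one constant label, all-distinct labels, random
track assignment — against any truth; only ARI is ~0 on all four, which is
why ARI drives every comparison in the package.

Method ranking across datasets uses an incremental Friedman procedure: with
methods ordered by mean rank, the Friedman chi-square p-value (classical
approximation, standard tie correction, rows re-ranked within each prefix)
is computed on the best two methods, then the best three, and so on; the
returned "top group" is the largest prefix whose p-value stays above the
significance level (default 0.05).  A fully tied matrix returns p = 1.  The
Iman–Davenport refinement is deliberately not applied.

## Baselines

Tracks-only (identity = track label), raw-feature clustering, and
track-centroid clustering with label propagation back to the detections
(which, like CBC, can only coarsen tracks).  Algorithms: k-means; average,
centroid, complete, median, single, ward and weighted linkage; Gaussian
mixtures with diagonal covariances and a 1000-iteration cap (seeded k-means
initialization); spectral clustering; DBSCAN swept over
ε ∈ {0.5, 1.0, …, 4.0} × MinPts ∈ {1, …, 8}, keeping the run whose cluster
count is closest to the requested K (ties to smaller ε, then smaller
MinPts), with noise points returned as singleton clusters.  FINCH is
recognised as a method name but reported unsupported unless an external
implementation is wrapped in.

## Synthetic data

The generator emulates the target regime, not photorealism.  Rendered scenes
place elliptical "animals" with per-identity base colours (hue-wheel palette
scaled to a requested mean pairwise colour distance) and per-pixel Gaussian
texture noise on a noisy background; motion is a Gaussian random walk;
occlusion is a painter's algorithm with fixed per-identity z-order; the
ground-truth box is the full ellipse extent clipped to the frame (annotators
draw the whole animal), dropped when under 3×3 visible pixels.  Two arenas:
*pen* reflects animals at the walls; *open* lets them exit and re-enter with
a per-frame re-entry probability.  Presets: **pen** (192×192, slow walk at
2 px/frame — a calm enclosure where overlap is rare and tracks stay pure),
**open** (128×128, 4 px/frame, exit/re-entry — fragmented, moderately noisy
tracks), **hard** (open with look-alike colours and strong noise).  Problem
sizes (5 identities, 80 frames) keep a full render–featurize–track–cluster
cycle around two seconds while producing hundreds of tracks, which is the
regime of interest.

The feature-space generator skips rendering: per-identity Gaussian means
placed so the closest pair is `separation × spread` apart, optional per-track
mean drift (appearance change over time), each identity's frame span split
into `fragmentation` contiguous tracks, and a co-occurrence schedule
controlling how many identities are visible simultaneously (all, as in a
pen, by default; a rotating block window otherwise).  Exactly one detection
per visible identity per frame, so ground truth never violates the
frame constraint.  All randomness derives from one seed through named
substreams (motion, appearance, schedule, texture), so components can be
varied independently and output is bit-reproducible.

What passing on this data does **not** show: real footage has deformable
bodies, lighting drift, annotation jitter and appearance so similar that
even humans label by position rather than looks; colour-separated ellipses
are easier than that, so absolute ARI values here do not transfer to real
videos.  The synthetic comparisons establish ordering and correctness
properties (constraint respect, coarsening, recovery when appearance is
informative), not field performance.

## Degenerate inputs and edge cases

Empty annotation files, non-positive box extents, length mismatches and
unfeaturized datasets raise validation errors naming the problem; malformed
CSV rows name the line.  Boxes partially outside an image are clamped before
gridding; fully outside is an error.  Association with an empty frame
returns an empty match set.  A merge-matrix request with fewer than two
labels is an error.  The DBSCAN sweep with all points flagged as noise
returns all singletons.

## Known limitations

* Tracks are never split, so an impure input track (two animals swapped
  during a crossing) caps achievable accuracy and can CL-block legitimate
  merges.
* Resubstitution with nearest-centroid leaves outlier singleton tracks
  sticky (see above); a different plug-in classifier trades speed for less
  stickiness.
* CL constraints use co-occurrence in ≥1 frame; a single frame of annotation
  error can permanently block a correct merge.
* The identity count K must be supplied; the algorithm treats it as exact.
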