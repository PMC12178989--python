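# trackreid

Re-identification of individual animals in short videos by **post-clustering
the output of a multiple-object tracker**.

## The problem

A multiple-object tracker (MOT) follows animals across frames and emits, for
every bounding box *z*, a frame number *Fr(z)*, coordinates *[x, y, w, h]*, and
a track label *Tr(z)*.  Ideally each track would be one animal, but animals
leave the camera view, re-enter, occlude one another and move abruptly, so a
single animal ends up scattered over many tracks — in fenced-pen footage it is
common to see hundreds of tracks for a few hundred boxes and fewer than ten
animals.  Conservation and husbandry applications need the opposite: a
**label map** assigning every box to one of roughly *K* known individuals.

`trackreid` builds that label map.  The key observation is that video supplies
constraints for free:

* **must-link** — boxes within one track are the same animal (trusted as-is);
* **cannot-link (CL)** — two boxes in the *same frame* are different animals,
  hence two tracks that ever share a frame can never be merged.

## Classifier-based clustering (CBC)

Given feature vectors *X = Fe(Z)*, frames *Y = Fr(Z)*, track labels
*L = Tr(Z)* and a target identity count *K* (if *K* ≥ the number of tracks,
the tracks are returned as-is), CBC repeats:

1. train a classifier *C* on *(X, L′)* using the current track labels *L′* as
   classes;
2. reclassify the training data (resubstitution) and form the confusion
   matrix *M*;
3. zero the diagonal of *M* (correct classifications carry no merge signal);
4. for every CL-constrained track pair *(p, q)* set *M(p,q) = M(q,p) = 0*;
5. scale each row of *M* to sum to 1, so *M(i,j)* is the *proportion* of
   track *i* relabelled as track *j*;
6. find the largest entry of *M*; if it is zero or only *K* tracks remain,
   stop — otherwise relabel the row track to the column track and go to 1.

A large row-scaled entry means "most of track *p* looks like track *q*", the
signature of one animal split across two tracks.  Because only whole tracks
are ever relabelled, the output is a coarsening of the input tracks, and the
loop performs at most *(n_tracks − K)* merges.  The classifier is pluggable;
the default is nearest-centroid, which tolerates the singleton tracks that
fragmented videos produce in bulk.

The package also provides:

* `features` — the 54-dimensional appearance descriptor (3×3 grid × RGB ×
  {mean, sd} per cell) used to represent each box;
* `tracker` — the BASIC track generator: IoU-gated (default 0.7) Hungarian
  association between consecutive frames;
* `metrics` — ARI, NMI, counting accuracy, Hungarian accuracy, a sanity
  battery of degenerate labelings showing why ARI is the metric that matters,
  and an incremental Friedman procedure for ranking methods across datasets;
* `baselines` — tracks-only, raw-feature clustering and track-centroid
  clustering with k-means, seven linkages, GMM, spectral and a DBSCAN
  parameter sweep;
* `synth` — synthetic scene and feature-track generators emulating the target
  regime (same-species animals, occlusion, exit/re-entry, fragmentation).

## Worked example

```python
from trackreid import FeatureTrackConfig, ari, cbc_cluster, simulate_feature_tracks

cfg = FeatureTrackConfig(n_identities=8, fragmentation=3, separation=5.0,
                         spread=1.0, seed=7)
ds = simulate_feature_tracks(cfg)
print(ari(ds.identity_labels(), ds.track_labels()))   # 0.4606
print(ari(ds.identity_labels(),
          cbc_cluster(ds, ds.track_labels(), K=8)))   # 1.0000
```

Eight identities are fragmented into 24 tracks; the raw tracks agree with the
truth only at ARI 0.46, while CBC merges the fragments back perfectly
(ARI = 1: the clusters coincide exactly with the identities).  The scripts in
`examples/` walk through each capability — rendering a scene, extracting the
descriptor, the metric battery, and a full pipeline comparison — and print
the numbers with interpretation.

There is also a thin CLI mirroring the library:

```bash
reid simulate --preset open --out scene --seed 1
reid pipeline --annotations scene/gt.csv --frames scene/frames \
              --k 5 --method cbc --out-dir run --frame-base 0
# ARI=0.7080 NMI=0.7347 ACC=1.0000 HACC=0.7143 (67 identities) -> run
```

(The open-arena scene fragments 5 animals into hundreds of tracks; CBC merges
what the cannot-link constraints and the classifier's confusions allow and
stops when nothing mergeable remains — here 67 clusters, most of them tiny
occlusion fragments, against a tracks-only ARI near 0.)

Annotations are MOTChallenge-style CSV (`frame, id, x, y, w, h`, extra
columns ignored); stage outputs (features, tracks, labels, metrics, manifest)
are plain files.

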