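"""End-to-end comparison on an open-arena scene: CBC vs alternatives.

Renders a scene where animals leave and re-enter the view, extracts
features, builds tracks, then compares identity maps from (a) the tracks
alone, (b) k-means on raw features, (c) ward linkage on track centroids,
and (d) classifier-based clustering.
"""

import numpy as np

from trackreid import (
    SCENE_PRESETS,
    ari,
    build_tracks,
    cbc_cluster,
    cluster_baseline,
    propagate_centroid_labels,
    simulate_scene,
    track_centroids,
)
from trackreid.features import extract_features, zscore

frames, ds = simulate_scene(SCENE_PRESETS["open"])
for det in ds:
    det.features = extract_features(frames[det.frame], det.box)
truth = ds.identity_labels()
K = np.unique(truth).size

tracks = build_tracks(ds)
ds = ds.with_tracks(tracks)
print(f"{len(ds)} boxes, {K} identities, {np.unique(tracks).size} tracks")

results = {"tracks-only": tracks}
results["raw k-means"] = cluster_baseline("kmeans", zscore(ds.feature_matrix()), K, seed=0)
cd = track_centroids(ds, tracks)
cent = cluster_baseline("ward", zscore(cd.centroids), K, seed=0)
results["centroid ward"] = propagate_centroid_labels(cent, tracks, cd.track_keys)
results["CBC"] = cbc_cluster(ds, tracks, K)

for name, labels in results.items():
    print(f"  ARI {name:14s} = {ari(truth, labels):.4f}")
print("higher is better; every post-clustering method far exceeds the raw")
print("tracks. CBC only ever merges whole tracks (it can never split one),")
print("so unlike the unconstrained baselines it is guaranteed to respect the")
print("frame constraints — on harder, less colour-separable footage that")
print("structure matters more than it does in this idealized scene")
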