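import numpy as np
import pytest

from trackreid import (
    BoundingBox,
    Detection,
    SceneConfig,
    TrackedDataset,
    build_tracks,
    cbc_cluster,
    simulate_scene,
)
from trackreid.features import extract_features


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(rows):
    """rows: (frame, track, identity, x, y, w, h) tuples -> TrackedDataset."""
    dets = [
        Detection(frame=f, box=BoundingBox(x, y, w, h), track=t, identity=i)
        for f, t, i, x, y, w, h in rows
    ]
    return TrackedDataset(dets)


def featurize_from_frames(dataset, frames):
    for det in dataset:
        det.features = extract_features(frames[det.frame], det.box)
    return dataset


def run_scene_pipeline(config: SceneConfig, K: int, threshold: float = 0.7):
    """Render -> featurize -> track -> CBC; returns (truth, tracks, labels)."""
    frames, ds = simulate_scene(config)
    featurize_from_frames(ds, frames)
    tracks = build_tracks(ds, threshold)
    labels = cbc_cluster(ds.with_tracks(tracks), tracks, K)
    return ds.identity_labels(), tracks, labels
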