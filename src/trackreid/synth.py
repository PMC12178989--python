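"""Synthetic multi-animal scenes and feature-space track datasets.

Real footage of same-species groups is scarce and hard to annotate, so the
generator emulates its regime at two levels.  :func:`simulate_scene` renders
ellipse "animals" with per-identity base colour and per-pixel texture noise
moving by a random walk, either fenced in a pen (reflecting bounds) or in an
open arena where animals exit the view and re-enter later; overlap produces
occlusion via a painter's z-order.  :func:`simulate_feature_tracks` skips
rendering and draws detections directly in feature space from per-identity
Gaussians, fragmenting each identity's frame span into several tracks and
scheduling which identities co-occur — exactly the inputs the clustering
stage consumes.

All randomness flows from a single seed through named substreams (motion,
appearance, schedule) so that one aspect can be varied while the others stay
fixed.
"""

from __future__ import annotations

import colorsys
import os
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import FEATURE_DIM, BoundingBox, Detection, TrackedDataset, ValidationError, write_labels

__all__ = [
    "SceneConfig",
    "FeatureTrackConfig",
    "simulate_scene",
    "simulate_scene_to_dir",
    "simulate_feature_tracks",
    "SCENE_PRESETS",
]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable across processes (crc32, not builtin hash)."""
    tag = zlib.crc32(name.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([seed % 2**31, tag]))


@dataclass
class SceneConfig:
    """Parameters of a rendered multi-animal scene.

    ``appearance_separation`` is the mean pairwise Euclidean distance
    between identity base colours (0-255 intensity units);
    ``texture_noise`` the per-pixel Gaussian sd; ``motion_step`` the
    random-walk step in pixels/frame.  ``arena="pen"`` reflects animals at
    the frame edges; ``arena="open"`` lets them leave and re-enter with
    probability ``reentry_prob`` per frame while out of view.
    """

    n_identities: int = 5
    n_frames: int = 80
    frame_size: tuple[int, int] = (128, 128)  # (width, height)
    animal_axes: tuple[float, float] = (11.0, 7.0)  # ellipse semi-axes (px)
    appearance_separation: float = 120.0
    texture_noise: float = 12.0
    motion_step: float = 4.0
    arena: str = "pen"
    reentry_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identities < 1:
            raise ValidationError("need at least one identity")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if self.arena not in ("pen", "open"):
            raise ValidationError(f"arena must be 'pen' or 'open', got {self.arena!r}")
        if not 0 <= self.reentry_prob <= 1:
            raise ValidationError("reentry_prob must be in [0, 1]")
        w, h = self.frame_size
        rx, ry = self.animal_axes
        if w < 2 * rx + 4 or h < 2 * ry + 4:
            raise ValidationError(
                f"frame {w}x{h} too small for animals with semi-axes {rx}x{ry}"
            )


def _identity_colors(n: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Base colours on the hue wheel, scaled to the requested mean distance."""
    hues = (np.arange(n) / max(n, 1) + rng.uniform(0, 1)) % 1.0
    palette = np.array([colorsys.hsv_to_rgb(h, 1.0, 1.0) for h in hues]) * 255.0
    if n == 1:
        return palette
    diffs = palette[:, None, :] - palette[None, :, :]
    d = np.sqrt((diffs**2).sum(-1))
    mean_d = d[np.triu_indices(n, 1)].mean()
    center = palette.mean(axis=0)
    scaled = center + (palette - center) * (separation / mean_d)
    return np.clip(scaled, 0, 255)


def simulate_scene(config: SceneConfig) -> tuple[list[np.ndarray], TrackedDataset]:
    """Render the scene; returns frame images and the ground-truth dataset.

    The ground-truth box of each animal is its full ellipse extent clipped
    to the frame (annotators draw the whole animal, occluded or not); boxes
    whose visible clip is smaller than 3x3 pixels are dropped.  Occlusion is
    a painter's algorithm with a fixed per-identity z-order.  Deterministic
    given the seed.
    """
    w, h = config.frame_size
    rx, ry = config.animal_axes
    n = config.n_identities
    motion = _stream(config.seed, "motion")
    appearance = _stream(config.seed, "appearance")
    noise_rng = _stream(config.seed, "texture")
    colors = _identity_colors(n, config.appearance_separation, appearance)

    pos = np.column_stack(
        [motion.uniform(rx + 1, w - rx - 1, n), motion.uniform(ry + 1, h - ry - 1, n)]
    )
    out_of_view = np.zeros(n, dtype=bool)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames: list[np.ndarray] = []
    detections: list[Detection] = []
    for f in range(config.n_frames):
        steps = motion.normal(scale=config.motion_step, size=(n, 2))
        for i in range(n):
            if out_of_view[i]:
                if motion.uniform() < config.reentry_prob:
                    # re-enter just inside a random edge
                    edge = motion.integers(4)
                    if edge == 0:
                        pos[i] = (motion.uniform(rx, w - rx), ry - ry / 2)
                    elif edge == 1:
                        pos[i] = (motion.uniform(rx, w - rx), h - ry / 2)
                    elif edge == 2:
                        pos[i] = (rx / 2, motion.uniform(ry, h - ry))
                    else:
                        pos[i] = (w - rx / 2, motion.uniform(ry, h - ry))
                    out_of_view[i] = False
                continue
            pos[i] += steps[i]
            if config.arena == "pen":
                pos[i, 0] = _reflect(pos[i, 0], rx + 1, w - rx - 1)
                pos[i, 1] = _reflect(pos[i, 1], ry + 1, h - ry - 1)

        img = np.full((h, w, 3), 90.0)
        img += noise_rng.normal(scale=config.texture_noise / 2, size=img.shape)
        for i in range(n):  # fixed z-order: later identities paint over earlier
            if out_of_view[i]:
                continue
            cx, cy = pos[i]
            mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
            if not mask.any():
                if config.arena == "open":
                    out_of_view[i] = True
                continue
            body = colors[i] + noise_rng.normal(
                scale=config.texture_noise, size=(int(mask.sum()), 3)
            )
            img[mask] = body
            x0, y0 = cx - rx, cy - ry
            box = BoundingBox(x0, y0, 2 * rx, 2 * ry)
            cx0 = max(0.0, x0)
            cy0 = max(0.0, y0)
            cw = min(float(w), x0 + 2 * rx) - cx0
            ch = min(float(h), y0 + 2 * ry) - cy0
            if cw < 3 or ch < 3:
                if config.arena == "open":
                    out_of_view[i] = True
                continue
            detections.append(Detection(frame=f, box=box, identity=i))
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
    if not detections:
        raise ValidationError("scene produced no visible detections; enlarge the frame")
    return frames, TrackedDataset(detections, n_frames=config.n_frames)


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    t = (v - lo) % (2 * span)
    return lo + (t if t <= span else 2 * span - t)


def simulate_scene_to_dir(config: SceneConfig, out_dir: str | os.PathLike) -> Path:
    """Render a scene to disk: numbered PNG frames plus gt.csv annotations."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames_dir = out / "frames"
    frames_dir.mkdir(exist_ok=True)
    frames, dataset = simulate_scene(config)
    for f, img in enumerate(frames):
        iio.imwrite(frames_dir / f"{f:06d}.png", img)
    write_labels(dataset, dataset.identity_labels(), out / "gt.csv", frame_base=0)
    return out


@dataclass
class FeatureTrackConfig:
    """Feature-space dataset: identities, fragmented tracks, co-occurrence.

    Identity means are placed so the *closest* pair is ``separation`` apart
    (in units of the within-identity sd ``spread``); per-track means drift
    from the identity mean by ``drift_scale`` to emulate appearance change
    over a video.  ``fragmentation`` is the number of tracks each identity's
    frame span is split into; ``co_occurrence`` is how many identities are
    visible simultaneously (default: all, as in a pen).
    """

    n_identities: int = 8
    n_frames: int = 120
    dim: int = FEATURE_DIM
    separation: float = 5.0
    spread: float = 1.0
    drift_scale: float = 0.0
    fragmentation: int = 3
    co_occurrence: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identities < 1 or self.n_frames < 1:
            raise ValidationError("need at least one identity and one frame")
        if self.fragmentation < 1:
            raise ValidationError("fragmentation rate must be >= 1")
        if self.co_occurrence is None:
            self.co_occurrence = self.n_identities
        if not 1 <= self.co_occurrence <= self.n_identities:
            raise ValidationError(
                f"cannot schedule {self.co_occurrence} simultaneous identities "
                f"out of {self.n_identities}"
            )
        if self.spread < 0 or self.separation < 0:
            raise ValidationError("spread and separation must be non-negative")
        if self.dim != FEATURE_DIM:
            raise ValidationError(f"feature dimension must be {FEATURE_DIM}")


def simulate_feature_tracks(config: FeatureTrackConfig) -> TrackedDataset:
    """Draw a featurized, tracked, ground-truth-labelled dataset.

    Every visible identity contributes exactly one detection per frame, so
    ground truth never places two same-identity detections in one frame.
    Track labels are global integers issued identity-major.
    """
    n, m = config.n_identities, config.co_occurrence
    appearance = _stream(config.seed, "appearance")
    schedule = _stream(config.seed, "schedule")
    noise = _stream(config.seed, "noise")

    means = appearance.normal(size=(n, config.dim))
    if n > 1:
        diffs = means[:, None, :] - means[None, :, :]
        d = np.sqrt((diffs**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        means *= (config.separation * config.spread) / d.min()

    # which identities are visible in each frame: rotating block window
    if m == n:
        present = {f: list(range(n)) for f in range(config.n_frames)}
    else:
        block = max(1, config.n_frames // n)
        present = {
            f: sorted(((f // block) + j) % n for j in range(m))
            for f in range(config.n_frames)
        }

    frames_of: dict[int, list[int]] = {i: [] for i in range(n)}
    for f in range(config.n_frames):
        for i in present[f]:
            frames_of[i].append(f)

    detections: list[Detection] = []
    next_track = 0
    for i in range(n):
        fr = frames_of[i]
        if not fr:
            continue
        chunks = [c for c in np.array_split(np.array(fr), config.fragmentation) if c.size]
        for chunk in chunks:
            track_mean = means[i] + config.drift_scale * appearance.normal(size=config.dim)
            for f in chunk:
                feats = track_mean + config.spread * noise.normal(size=config.dim)
                box = BoundingBox(x=10.0 * i, y=1.0 + (f % 7), w=5.0, h=5.0)
                detections.append(
                    Detection(
                        frame=int(f), box=box, track=next_track, identity=i, features=feats
                    )
                )
            next_track += 1
    detections.sort(key=lambda d: d.frame)
    return TrackedDataset(detections, n_frames=config.n_frames)


# pen: a fenced enclosure seen from above — animals spread out and amble, so
# overlap is rare and tracks stay pure.  open: a hand-held side view — faster
# motion, exits and re-entries, fragmented tracks.  hard: open arena with
# look-alike animals and strong texture noise.
SCENE_PRESETS: dict[str, SceneConfig] = {
    "pen": SceneConfig(arena="pen", frame_size=(192, 192), motion_step=2.0),
    "open": SceneConfig(arena="open"),
    "hard": SceneConfig(
        arena="open", appearance_separation=70.0, texture_noise=25.0, motion_step=6.0
    ),
}
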