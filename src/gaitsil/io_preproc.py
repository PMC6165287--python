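"""Reading, validation and normalization of binary silhouette sequences.

A walking pass is observed as an ordered stack of binary masks (foreground
walker = 1) taken from a lateral viewpoint. This module reads such stacks
from frame directories, normalizes every silhouette to a common height while
preserving aspect ratio (which makes all downstream pixel-valued features
robust to subject-to-camera distance), computes the feet-distance signal
(bounding-box width per frame) that drives gait-event detection, and
estimates the walking direction from the centroid drift.

Coordinate convention: origin top-left, x rightward, y downward; "more
elevated" therefore means smaller y. All indices are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.transform import resize

from .errors import NoNetTranslationError, SequenceError

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".pgm", ".pbm", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


class SilhouetteFrame(NamedTuple):
    """A single binary silhouette mask with its frame ordinal."""

    mask: np.ndarray
    index: int


@dataclass(eq=False)
class SilhouetteSequence:
    """Ordered binary silhouette masks of one walking pass.

    Attributes
    ----------
    frames:
        ``(T, H, W)`` uint8 array with values in {0, 1}.
    fps:
        Frame rate in frames per second.
    camera_side:
        Which body side faces the camera (``"left"`` or ``"right"``); a
        configuration input, required to map near/far feet to left/right.
    walking_direction:
        ``"leftward"`` / ``"rightward"`` if known, else ``None``.
    """

    frames: np.ndarray
    fps: float
    camera_side: str = "right"
    walking_direction: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SequenceError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise SequenceError("a silhouette sequence requires >=2 frames")
        if self.fps <= 0:
            raise SequenceError("fps must be > 0")
        if self.camera_side not in ("left", "right"):
            raise SequenceError("camera_side must be 'left' or 'right'")
        vals = np.unique(self.frames)
        if not np.isin(vals, (0, 1)).all():
            raise SequenceError("masks must be strictly binary (0/1)")
        self.frames = self.frames.astype(np.uint8, copy=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, t: int) -> SilhouetteFrame:
        return SilhouetteFrame(self.frames[t], t)

    def mirrored(self) -> "SilhouetteSequence":
        """Horizontally mirrored copy (walking direction flips; which body
        side faces the camera flips with it)."""
        direction = None
        if self.walking_direction is not None:
            direction = (
                "leftward" if self.walking_direction == "rightward" else "rightward"
            )
        return SilhouetteSequence(
            frames=self.frames[:, :, ::-1].copy(),
            fps=self.fps,
            camera_side="left" if self.camera_side == "right" else "right",
            walking_direction=direction,
        )


@dataclass(eq=False)
class FeetDistanceSignal:
    """Per-frame silhouette bounding-box width, the feet-distance proxy."""

    width: np.ndarray
    smoothed: np.ndarray
    fps: float
    window: int = field(default=1)

    def __post_init__(self) -> None:
        self.width = np.asarray(self.width, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if self.width.shape != self.smoothed.shape:
            raise SequenceError("width and smoothed must have equal length")

    def __len__(self) -> int:
        return len(self.width)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Tight bounding box (r0, r1, c0, c1), inclusive; None for empty masks."""
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def read_silhouette_sequence(
    path: str | Path,
    fps: float,
    camera_side: str = "right",
) -> SilhouetteSequence:
    """Read a directory of per-frame mask images, in filename order.

    Any nonzero pixel becomes foreground; multi-channel images are reduced by
    "any channel nonzero". All frames must share one shape.
    """
    path = Path(path)
    if not path.is_dir():
        raise SequenceError(f"not a directory: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if len(files) == 0:
        raise SequenceError(f"no image frames found in {path}")
    if len(files) < 2:
        raise SequenceError(">=2 frames required")
    masks = []
    for p in files:
        try:
            img = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise SequenceError(f"cannot decode frame {p.name}: {exc}") from exc
        if img.ndim == 3:
            img = img.any(axis=-1)
        if img.ndim != 2:
            raise SequenceError(f"frame {p.name} is not a 2-D image")
        masks.append((img != 0).astype(np.uint8))
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise SequenceError(f"frames have differing shapes: {sorted(shapes)}")
    return SilhouetteSequence(np.stack(masks), fps=fps, camera_side=camera_side)


def write_silhouette_sequence(seq: SilhouetteSequence, path: str | Path) -> None:
    """Write a sequence as zero-padded 1-bit PNG frames (inverse of read)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t in range(seq.n_frames):
        iio.imwrite(path / f"frame_{t:05d}.png", seq.frames[t] * np.uint8(255))


def normalize_height(
    seq: SilhouetteSequence,
    height: int = 200,
    max_invalid_fraction: float = 0.2,
) -> SilhouetteSequence:
    """Rescale every silhouette so its bounding box is ``height`` px tall.

    Aspect ratio is preserved, the box bottom is placed on a common baseline
    (the last canvas row) and the horizontal trajectory is kept by mapping
    each frame's bounding-box center through its own scale factor. Empty
    frames are dropped (an error is raised if more than
    ``max_invalid_fraction`` of the frames are empty). The operation is
    idempotent: normalizing an already-normalized sequence is pixel-identical.
    """
    scaled: list[np.ndarray] = []
    lefts: list[int] = []
    n_invalid = 0
    for t in range(seq.n_frames):
        box = _bbox(seq.frames[t])
        if box is None:
            n_invalid += 1
            logger.warning("frame %d empty, excluded from normalization", t)
            continue
        r0, r1, c0, c1 = box
        crop = seq.frames[t][r0 : r1 + 1, c0 : c1 + 1]
        h = r1 - r0 + 1
        scale = height / h
        if h == height:
            out = crop.astype(np.uint8)
        else:
            w_new = max(1, round(crop.shape[1] * scale))
            out = (
                resize(
                    crop.astype(float),
                    (height, w_new),
                    order=1,
                    anti_aliasing=False,
                )
                >= 0.5
            ).astype(np.uint8)
            if not out.any():  # pathologically thin shape collapsed
                n_invalid += 1
                logger.warning("frame %d collapsed under rescale, excluded", t)
                continue
        center = (c0 + c1 + 1) / 2 * scale
        lefts.append(round(center - out.shape[1] / 2))
        scaled.append(out)
    if n_invalid > max_invalid_fraction * seq.n_frames:
        raise SequenceError(
            f"{n_invalid}/{seq.n_frames} frames invalid (empty); "
            f"more than {max_invalid_fraction:.0%} allowed"
        )
    if len(scaled) < 2:
        raise SequenceError("fewer than 2 valid frames after normalization")
    shift = -min(lefts)
    width = max(left + shift + m.shape[1] for left, m in zip(lefts, scaled))
    canvas = np.zeros((len(scaled), height, width), dtype=np.uint8)
    for i, (left, m) in enumerate(zip(lefts, scaled)):
        x0 = left + shift
        canvas[i, :, x0 : x0 + m.shape[1]] = m
    return SilhouetteSequence(
        canvas,
        fps=seq.fps,
        camera_side=seq.camera_side,
        walking_direction=seq.walking_direction,
    )


def compute_feet_distance_signal(
    seq: SilhouetteSequence,
    window: int | None = None,
) -> FeetDistanceSignal:
    """Bounding-box width per frame, plus a centered moving-average copy.

    The width of the tightest box around the silhouette approximates the
    distance between the two feet: it peaks when the feet are spread at
    initial contact and dips when they pass each other. The default smoothing
    window is ``round(fps / 6)`` frames (5 at 30 fps).
    """
    widths = np.empty(seq.n_frames, dtype=float)
    for t in range(seq.n_frames):
        box = _bbox(seq.frames[t])
        if box is None:
            raise SequenceError(f"frame {t} is empty; normalize/validate first")
        _, _, c0, c1 = box
        widths[t] = c1 - c0 + 1
    if window is None:
        window = max(1, round(seq.fps / 6))
    window = max(1, int(window))
    smoothed = uniform_filter1d(widths, size=window, mode="nearest")
    return FeetDistanceSignal(widths, smoothed, fps=seq.fps, window=window)


def estimate_walking_direction(
    seq: SilhouetteSequence,
    eps: float = 0.05,
) -> str:
    """Direction of net translation from the centroid-x least-squares slope.

    Returns ``"rightward"`` for a positive slope, ``"leftward"`` for a
    negative one; raises :class:`NoNetTranslationError` when the absolute
    slope is below ``eps`` px/frame.
    """
    cx = np.empty(seq.n_frames, dtype=float)
    for t in range(seq.n_frames):
        ys, xs = np.nonzero(seq.frames[t])
        if xs.size == 0:
            raise SequenceError(f"frame {t} is empty")
        cx[t] = xs.mean()
    slope = np.polyfit(np.arange(seq.n_frames), cx, 1)[0]
    if not math.isfinite(slope) or abs(slope) < eps:
        raise NoNetTranslationError(
            f"no net translation (|slope|={abs(slope):.4f} px/frame < {eps})"
        )
    return "rightward" if slope > 0 else "leftward"


def with_direction(seq: SilhouetteSequence, eps: float = 0.05) -> SilhouetteSequence:
    """Copy of ``seq`` with ``walking_direction`` filled in if missing."""
    if seq.walking_direction is not None:
        return seq
    return replace(seq, walking_direction=estimate_walking_direction(seq, eps=eps))
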