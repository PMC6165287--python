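"""Body-related biomechanical features from gait energy images.

A gait energy image (GEI) is the pixelwise mean of bounding-box-aligned
silhouettes over a (half) gait cycle: stationary body parts stay bright,
moving parts blur into intermediate grays. Three features are derived:

* amount of movement (AOM) — the Shannon entropy of the horizontal
  adjacent-pixel differences of a mid-stance/mid-swing half-cycle GEI;
  restricted limbs blur less and produce a poorer difference histogram,
  hence lower entropy;
* shift in center of gravity — the horizontal offset between the
  intensity-weighted centroid of the full-cycle GEI (COG) and the centroid
  of its bottom feet band (center of support, COS); a hunched posture pushes
  the COG off the base of support;
* torso orientation — the angle between the horizontal axis and the first
  principal component of the torso band of the full-cycle GEI; upright
  walkers score near 90 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .cycles import Interval
from .errors import DegenerateInputError
from .io_preproc import SilhouetteSequence, _bbox


@dataclass(eq=False)
class GEIImage:
    """Mean of ``P`` aligned silhouette crops; values in [0, 1]."""

    grid: np.ndarray
    scope: str  # "half_cycle" | "full_cycle"
    P: int
    side: str | None = None


class COGResult(NamedTuple):
    shift: float
    cog: tuple[float, float]
    cos: tuple[float, float]


def compute_gei(
    seq: SilhouetteSequence,
    interval: Interval,
    scope: str = "half_cycle",
) -> GEIImage:
    """GEI over frames ``[a, b)``.

    Every frame is cropped to its silhouette bounding box and placed on a
    common canvas with the box bottom on the baseline and the silhouette's
    horizontal centroid on a common column (the classic gait-energy-image
    alignment: the mostly static trunk stays crisp while moving limbs blur).
    """
    a, b = interval
    if b <= a:
        raise DegenerateInputError(f"empty interval [{a}, {b})")
    if a < 0 or b > seq.n_frames:
        raise DegenerateInputError(f"interval [{a}, {b}) outside sequence")
    crops = []
    for t in range(a, b):
        box = _bbox(seq.frames[t])
        if box is None:
            continue
        r0, r1, c0, c1 = box
        crop = seq.frames[t][r0 : r1 + 1, c0 : c1 + 1]
        cx = float(np.nonzero(crop)[1].mean())
        crops.append((crop, cx))
    if not crops:
        raise DegenerateInputError(f"no nonempty frames in [{a}, {b})")
    height = max(c.shape[0] for c, _ in crops)
    ref = max(int(round(cx)) for _, cx in crops)
    width = max(ref + c.shape[1] - int(round(cx)) for c, cx in crops)
    acc = np.zeros((height, width), dtype=float)
    for c, cx in crops:
        h, w = c.shape
        left = ref - int(round(cx))
        acc[height - h :, left : left + w] += c
    return GEIImage(grid=acc / len(crops), scope=scope, P=len(crops))


def compute_amount_of_movement(gei: GEIImage, levels: int = 256) -> float:
    """Entropy (bits) of horizontal adjacent-pixel differences of the GEI.

    The GEI is quantized to ``levels`` gray values; within the silhouette
    bounding box, each right-neighbor pixel pair contributes its difference
    to a histogram whose Shannon entropy is the amount of movement. A
    constant GEI yields a single difference value and 0 bits.
    """
    grid = gei.grid
    box = _bbox(grid > 0)
    if box is None:
        return 0.0
    r0, r1, c0, c1 = box
    region = np.round(grid[r0 : r1 + 1, c0 : c1 + 1] * (levels - 1))
    if region.shape[1] < 2:
        return 0.0
    diffs = (region[:, 1:] - region[:, :-1]).ravel()
    _, counts = np.unique(diffs, return_counts=True)
    p = counts / diffs.size
    return float(-(p * np.log2(p)).sum())


def compute_aom_symmetry(
    aom_left: list[float], aom_right: list[float]
) -> float:
    """Absolute difference of the per-side amount-of-movement medians."""
    if len(aom_left) == 0 or len(aom_right) == 0:
        raise DegenerateInputError("need >=1 amount-of-movement value per side")
    return float(abs(np.median(aom_left) - np.median(aom_right)))


def compute_cog_shift(
    gei_full: GEIImage,
    feet_fraction: float = 0.10,
) -> COGResult:
    """Horizontal offset between the COG and the center of support.

    COG is the intensity-weighted centroid of the full-cycle GEI; COS the
    intensity-weighted centroid of the bottom ``feet_fraction`` of the
    silhouette's row extent (the feet band).
    """
    grid = gei_full.grid
    total = grid.sum()
    if total == 0:
        raise DegenerateInputError("empty GEI")
    ys, xs = np.indices(grid.shape)
    cog = (float((grid * xs).sum() / total), float((grid * ys).sum() / total))
    rows = np.flatnonzero(grid.any(axis=1))
    r1 = rows[-1]
    n_band = math.ceil(feet_fraction * (r1 - rows[0] + 1))
    band = grid[r1 + 1 - n_band : r1 + 1]
    band_total = band.sum()
    if band_total == 0:
        raise DegenerateInputError("empty feet band in GEI")
    bys, bxs = np.indices(band.shape)
    cos = (
        float((band * bxs).sum() / band_total),
        float((band * bys).sum() / band_total + (r1 + 1 - n_band)),
    )
    return COGResult(shift=abs(cog[0] - cos[0]), cog=cog, cos=cos)


def compute_torso_orientation(
    gei_full: GEIImage,
    top_fraction: float = 0.13,
    bottom_fraction: float = 0.47,
) -> float:
    """Angle (deg, in [0, 90]) of the torso's first principal axis.

    The torso band spans rows between ``top_fraction`` and
    ``bottom_fraction`` of the silhouette height from the top (head about the
    top 13%, hip near 47%). Pixel coordinates in the band are summarized by
    their GEI-intensity-weighted covariance; the angle between the horizontal
    axis and the leading eigenvector, folded into [0, 90] by taking absolute
    components, is the torso orientation.
    """
    grid = gei_full.grid
    box = _bbox(grid > 0)
    if box is None:
        raise DegenerateInputError("empty GEI")
    r0, r1, _, _ = box
    height = r1 - r0 + 1
    band_top = r0 + round(top_fraction * height)
    band_bot = r0 + round(bottom_fraction * height)
    band = grid[band_top:band_bot]
    weights = band.ravel()
    mass = weights.sum()
    if band.size == 0 or mass == 0 or (weights > 0).sum() < 2:
        raise DegenerateInputError("degenerate torso band")
    ys, xs = np.indices(band.shape)
    xs = xs.ravel().astype(float)
    ys = ys.ravel().astype(float)
    mx = (weights * xs).sum() / mass
    my = (weights * ys).sum() / mass
    dx = xs - mx
    dy = ys - my
    cov = np.array(
        [
            [(weights * dx * dx).sum(), (weights * dx * dy).sum()],
            [(weights * dx * dy).sum(), (weights * dy * dy).sum()],
        ]
    ) / mass
    if np.allclose(cov, 0):
        raise DegenerateInputError("zero covariance in torso band")
    evals, evecs = np.linalg.eigh(cov)
    pcx, pcy = evecs[:, int(np.argmax(evals))]
    return float(math.degrees(math.atan2(abs(pcy), abs(pcx))))
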