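"""Feet-related biomechanical features.

The anchor of every feet feature is the foot-flat footprint: during the first
part of the stance phase the sole is in complete ground contact, so within a
contact-delimited half cycle the stationary foot accumulates intensity in the
average feet image (AFI) — the pixelwise mean of the bottom feet band of the
silhouettes — while the swinging foot smears out. Otsu thresholding of the
AFI isolates that footprint even when short strides keep the feet partly
self-occluded. Footprint centroids then give step lengths (left/right via the
near/far elevation cue), a symmetry score, the normalized step count
(steps per pixel travelled), the walking speed, and the foot-flat ratio (the
fraction of stance spent flat-footed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import median

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .cycles import GaitEvents, Interval
from .errors import (
    DegenerateInputError,
    InsufficientStepsError,
    NoFootFlatWarning,
    SideAssignmentWarning,
)
from .io_preproc import SilhouetteSequence


@dataclass(eq=False)
class AverageFeetImage:
    """Pixelwise mean of the feet band over one contact-delimited half cycle.

    ``grid`` covers the bottom feet band only; ``row_offset`` is the full
    frame row of the band's first row, so band coordinates can be mapped back.
    """

    grid: np.ndarray
    T: int
    interval: Interval
    row_offset: int


@dataclass(eq=False)
class FootFlat:
    """One thresholded foot-flat footprint.

    ``mask`` lives in feet-band coordinates; ``centroid`` is ``(x, y)`` in
    full normalized-frame coordinates. ``side`` is filled by
    :func:`assign_foot_sides`.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    ordinal: int
    interval: Interval
    row_offset: int
    ic_frame: int
    side: str | None = None

    def full_frame_mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(frame_shape, dtype=bool)
        band_h = self.mask.shape[0]
        out[self.row_offset : self.row_offset + band_h, : self.mask.shape[1]] = (
            self.mask
        )
        return out


@dataclass(eq=False)
class StepSeries:
    """Per-sequence feet-feature bundle."""

    SL_left: list[float]
    SL_right: list[float]
    SL_symm: float
    k: int
    C: float
    S: float
    FFR_left: float
    FFR_right: float


def compute_afi(
    seq: SilhouetteSequence,
    interval: Interval,
    band_fraction: float = 0.10,
) -> AverageFeetImage:
    """Average feet image over frames ``[a, b)``.

    The feet band is the bottom ``band_fraction`` of the frame height
    (``ceil`` of the row count), per the standard human-anatomy ratio.
    """
    a, b = interval
    if b <= a:
        raise DegenerateInputError(f"empty interval [{a}, {b})")
    if a < 0 or b > seq.n_frames:
        raise DegenerateInputError(f"interval [{a}, {b}) outside sequence")
    height = seq.frames.shape[1]
    n_band = math.ceil(band_fraction * height)
    grid = seq.frames[a:b, height - n_band :, :].mean(axis=0)
    return AverageFeetImage(grid=grid, T=b - a, interval=(a, b), row_offset=height - n_band)


def otsu_threshold_nonzero(grid: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over the nonzero values of ``grid`` (256-bin histogram).

    Restricting to nonzero values keeps the dominant background from swamping
    the histogram. Ties between equal-variance cuts resolve to the lowest
    threshold (argmax convention).
    """
    vals = grid[grid > 0]
    if vals.size == 0 or vals.max() == vals.min():
        raise DegenerateInputError("uniform or empty image; no threshold exists")
    return float(threshold_otsu(vals, nbins=nbins))


def extract_foot_flat(
    afi: AverageFeetImage,
    ordinal: int = 0,
    ic_frame: int | None = None,
) -> FootFlat | None:
    """Footprint = largest 8-connected component at/above the Otsu threshold.

    Returns ``None`` (with :class:`NoFootFlatWarning`) when the AFI is
    uniform/empty, so a half cycle can be skipped without aborting the
    sequence. The centroid is the unweighted mean of footprint pixel
    coordinates, reported in full-frame ``(x, y)``.
    """
    try:
        thresh = otsu_threshold_nonzero(afi.grid)
    except DegenerateInputError:
        warnings.warn(
            f"half cycle {afi.interval}: no foot flat detected (uniform AFI)",
            NoFootFlatWarning,
            stacklevel=2,
        )
        return None
    candidates = afi.grid >= thresh
    if not candidates.any():
        warnings.warn(
            f"half cycle {afi.interval}: no foot flat detected (empty candidates)",
            NoFootFlatWarning,
            stacklevel=2,
        )
        return None
    labels = cc_label(candidates, connectivity=2)
    largest = 1 + np.argmax(np.bincount(labels.ravel())[1:])
    mask = labels == largest
    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()), float(ys.mean() + afi.row_offset))
    return FootFlat(
        mask=mask,
        centroid=centroid,
        ordinal=ordinal,
        interval=afi.interval,
        row_offset=afi.row_offset,
        ic_frame=afi.interval[0] if ic_frame is None else ic_frame,
    )


def assign_foot_sides(
    flats: list[FootFlat],
    walking_direction: str | None = None,
    camera_side: str = "right",
) -> list[FootFlat]:
    """Label footprints left/right from the near/far elevation cue.

    Lacking depth, the foot farther from the camera appears more elevated
    (smaller centroid y). Each consecutive pair votes on the alternation
    parity; the majority fixes it (ties within a pair are skipped). The near
    foot maps to ``camera_side``, the far foot to the opposite side.
    ``walking_direction`` is accepted for interface symmetry; the elevation
    cue itself does not depend on it.
    """
    del walking_direction  # near/far mapping depends on camera side only
    if len(flats) < 2:
        raise InsufficientStepsError("need >=2 foot flats to assign sides")
    votes: list[bool] = []  # each True = "flat 0 is the far foot"
    for i in range(len(flats) - 1):
        yi = flats[i].centroid[1]
        yj = flats[i + 1].centroid[1]
        if yi == yj:
            continue
        i_is_far = yi < yj
        votes.append(i_is_far if i % 2 == 0 else not i_is_far)
    if not votes:
        raise DegenerateInputError("all footprint pairs tie in elevation")
    n_far = sum(votes)
    if 0 < n_far < len(votes):
        warnings.warn(
            f"foot-side votes not unanimous ({n_far}/{len(votes)} for far-first); "
            "parity chosen by majority",
            SideAssignmentWarning,
            stacklevel=2,
        )
    flat0_far = n_far * 2 > len(votes)
    near_side = camera_side
    far_side = "left" if camera_side == "right" else "right"
    for i, flat in enumerate(flats):
        is_far = flat0_far if i % 2 == 0 else not flat0_far
        flat.side = far_side if is_far else near_side
    return flats


def compute_step_lengths(
    flats: list[FootFlat],
) -> tuple[list[float], list[float], float]:
    """Step lengths from consecutive footprint centroids.

    Step ``i`` is the Euclidean distance between the centroids of footprints
    ``i`` and ``i+1`` and belongs to the side of the arriving foot
    (footprint ``i+1``). The symmetry score is the absolute difference of the
    side medians.
    """
    if len(flats) < 2:
        raise InsufficientStepsError("need >=2 foot flats to measure steps")
    if any(f.side is None for f in flats):
        raise InsufficientStepsError("assign_foot_sides must run first")
    sl: dict[str, list[float]] = {"left": [], "right": []}
    for i in range(len(flats) - 1):
        (x0, y0), (x1, y1) = flats[i].centroid, flats[i + 1].centroid
        sl[flats[i + 1].side].append(math.hypot(x1 - x0, y1 - y0))
    if not sl["left"] or not sl["right"]:
        raise InsufficientStepsError(
            "insufficient steps: need at least one step per side"
        )
    symm = abs(median(sl["left"]) - median(sl["right"]))
    return sl["left"], sl["right"], float(symm)


def compute_normalized_step_count(
    flats: list[FootFlat] | int,
    steps: list[float],
) -> float:
    """Foot-flat count divided by total distance travelled (steps/px)."""
    k = flats if isinstance(flats, int) else len(flats)
    if k < 2:
        raise InsufficientStepsError("need >=2 foot flats")
    total = float(np.sum(steps))
    if total <= 0:
        raise DegenerateInputError("zero total distance travelled")
    return k / total


def compute_speed(steps: list[float], d: float) -> float:
    """Total distance travelled over the first-to-last-contact duration."""
    if d <= 0:
        raise DegenerateInputError("duration d must be > 0")
    return float(np.sum(steps)) / d


def compute_foot_flat_ratio(
    seq: SilhouetteSequence,
    flat: FootFlat,
    events: GaitEvents,
    coverage_full: float = 0.95,
    coverage_partial: float = 0.50,
) -> float | None:
    """Fraction of the stance phase spent with the sole fully on the ground.

    Per frame from the footprint's initial contact, coverage is the fraction
    of footprint pixels inside the silhouette. Frames with coverage >=
    ``coverage_full`` count as flat foot; the stance phase runs until the last
    frame with coverage >= ``coverage_partial`` (a toe-off proxy). The search
    window ends at the same foot's next initial contact (two contacts ahead)
    so a later pass of the other foot cannot extend the stance. Returns
    ``None`` when no frame reaches partial coverage (degenerate footprint).
    """
    footprint = flat.full_frame_mask(seq.frame_shape)
    n_fp = footprint.sum()
    if n_fp == 0:
        return None
    ics = events.initial_contacts
    pos = int(np.searchsorted(ics, flat.ic_frame))
    end = int(ics[pos + 2]) if pos + 2 < len(ics) else seq.n_frames
    window = seq.frames[flat.ic_frame : end]
    coverage = window[:, footprint].sum(axis=1) / n_fp
    flat_duration = int((coverage >= coverage_full).sum())
    covered = np.flatnonzero(coverage >= coverage_partial)
    if covered.size == 0:
        return None
    stance_duration = int(covered[-1]) + 1
    return float(np.clip(flat_duration / stance_duration, 0.0, 1.0))


def compute_ffr_per_side(
    seq: SilhouetteSequence,
    flats: list[FootFlat],
    events: GaitEvents,
    coverage_full: float = 0.95,
    coverage_partial: float = 0.50,
) -> tuple[float, float]:
    """Median foot-flat ratio per side over all usable footprints."""
    per_side: dict[str, list[float]] = {"left": [], "right": []}
    for flat in flats:
        if flat.side is None:
            raise InsufficientStepsError("assign_foot_sides must run first")
        ffr = compute_foot_flat_ratio(
            seq, flat, events, coverage_full=coverage_full,
            coverage_partial=coverage_partial,
        )
        if ffr is not None:
            per_side[flat.side].append(ffr)
    if not per_side["left"] or not per_side["right"]:
        raise InsufficientStepsError("no usable foot-flat ratio on one side")
    return float(median(per_side["left"])), float(median(per_side["right"]))
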