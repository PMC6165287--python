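"""Gait-event detection and half-cycle segmentation.

Initial contacts (heel strikes) are approximated as maxima of the smoothed
feet-distance signal: the bounding box is widest when the feet are spread at
heel strike. Mid-stance/mid-swing instants are the minima between consecutive
contacts, where the feet pass each other. Contact-delimited half cycles feed
the feet features (average feet image); mid-delimited half cycles feed the
amount-of-movement entropy, because they bracket the weight transfer from one
side of the body to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientCyclesError
from .io_preproc import FeetDistanceSignal

Interval = tuple[int, int]


@dataclass(eq=False)
class GaitEvents:
    """Detected gait events of one walking pass.

    ``half_cycles_ic`` are ``[IC_i, IC_{i+1})`` frame intervals between
    consecutive initial contacts; ``half_cycles_mid`` the analogous intervals
    between consecutive midpoints. ``d`` is the duration in seconds between
    the first and last initial contacts.
    """

    initial_contacts: np.ndarray
    midpoints: np.ndarray
    fps: float
    d: float = field(init=False)
    half_cycles_ic: list[Interval] = field(init=False)
    half_cycles_mid: list[Interval] = field(init=False)

    def __post_init__(self) -> None:
        ics = np.asarray(self.initial_contacts, dtype=int)
        mids = np.asarray(self.midpoints, dtype=int)
        if ics.size < 2:
            raise InsufficientCyclesError("need >=2 initial contacts")
        if np.any(np.diff(ics) <= 0) or np.any(np.diff(mids) <= 0):
            raise InsufficientCyclesError("event lists must be strictly increasing")
        self.initial_contacts = ics
        self.midpoints = mids
        self.d = float(ics[-1] - ics[0]) / self.fps
        self.half_cycles_ic = [
            (int(a), int(b)) for a, b in zip(ics[:-1], ics[1:])
        ]
        self.half_cycles_mid = [
            (int(a), int(b)) for a, b in zip(mids[:-1], mids[1:])
        ]

    def full_cycles(self) -> list[Interval]:
        """``[IC_i, IC_{i+2})`` intervals, one full gait cycle each."""
        ics = self.initial_contacts
        return [(int(ics[i]), int(ics[i + 2])) for i in range(len(ics) - 2)]


def detect_initial_contacts(
    signal: FeetDistanceSignal,
    fps: float | None = None,
    min_separation_s: float = 0.25,
    prominence: float = 5.0,
) -> np.ndarray:
    """Local maxima of the smoothed feet-distance signal.

    Peaks must be at least ``min_separation_s`` apart (a half cycle is >=
    0.25 s even in fast gait) and at least ``prominence`` px prominent. Peaks
    at the first/last frame cannot arise (incomplete cycles are discarded by
    construction of ``find_peaks``).
    """
    fps = signal.fps if fps is None else fps
    min_sep = max(1, round(min_separation_s * fps))
    if len(signal) < 2 * min_sep:
        raise InsufficientCyclesError(
            f"signal too short ({len(signal)} frames) for event detection"
        )
    peaks, _ = find_peaks(signal.smoothed, distance=min_sep, prominence=prominence)
    if peaks.size < 2:
        raise InsufficientCyclesError(
            f"insufficient gait cycles: {peaks.size} initial contact(s) found"
        )
    return peaks.astype(int)


def detect_midpoints(
    signal: FeetDistanceSignal,
    initial_contacts: np.ndarray,
) -> np.ndarray:
    """One smoothed-signal minimum strictly inside each contact pair.

    Plateau ties resolve to the earliest minimizing frame (determinism).
    """
    ics = np.asarray(initial_contacts, dtype=int)
    if ics.size < 2:
        raise InsufficientCyclesError("need >=2 initial contacts")
    mids = []
    for a, b in zip(ics[:-1], ics[1:]):
        if b - a < 2:
            raise InsufficientCyclesError(
                f"no interior frames between contacts {a} and {b}"
            )
        inner = signal.smoothed[a + 1 : b]
        mids.append(a + 1 + int(np.argmin(inner)))
    return np.asarray(mids, dtype=int)


def segment_half_cycles(
    initial_contacts: np.ndarray,
    midpoints: np.ndarray,
    fps: float,
) -> GaitEvents:
    """Bundle event lists into :class:`GaitEvents` (computes ``d``)."""
    return GaitEvents(
        initial_contacts=np.asarray(initial_contacts, dtype=int),
        midpoints=np.asarray(midpoints, dtype=int),
        fps=fps,
    )


def detect_gait_events(
    signal: FeetDistanceSignal,
    fps: float | None = None,
    min_separation_s: float = 0.25,
    prominence: float = 5.0,
) -> GaitEvents:
    """Convenience chain: contacts, midpoints, segmentation."""
    fps = signal.fps if fps is None else fps
    ics = detect_initial_contacts(
        signal, fps, min_separation_s=min_separation_s, prominence=prominence
    )
    mids = detect_midpoints(signal, ics)
    return segment_half_cycles(ics, mids, fps)
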