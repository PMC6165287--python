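"""End-to-end feature extraction: silhouette sequence -> 12-feature vector.

Chains normalization, the feet-distance signal, gait-event detection, the
foot-flat features and the GEI body features into one call, producing the
per-sequence feature vector the classifier consumes:

SL_left, SL_right, SL_symm, FFR_left, FFR_right, S, C, TO, COG_shift,
AOM_left, AOM_right, AOM_symm.
"""

from __future__ import annotations

import logging
from statistics import median

import numpy as np
import pandas as pd

from . import body_features as bf
from . import cycles as cy
from . import feet_features as ff
from . import io_preproc as iop
from .config import PipelineConfig
from .errors import InsufficientCyclesError, InsufficientStepsError
from .stats_classify import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


def extract_features(
    seq: iop.SilhouetteSequence,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Compute the 12 biomechanical features of one walking pass."""
    cfg = config or PipelineConfig()
    norm = iop.normalize_height(seq, height=cfg.height)
    if norm.walking_direction is None:
        norm = iop.with_direction(norm, eps=cfg.direction_eps)
    signal = iop.compute_feet_distance_signal(norm, window=cfg.smoothing_window)
    events = cy.detect_gait_events(
        signal,
        min_separation_s=cfg.min_peak_separation_s,
        prominence=cfg.peak_prominence,
    )
    if len(events.initial_contacts) < 3:
        raise InsufficientCyclesError("need >=3 initial contacts for full cycles")

    # foot flats, one per contact-delimited half cycle
    flats = []
    for ordinal, interval in enumerate(events.half_cycles_ic):
        afi = ff.compute_afi(norm, interval, band_fraction=cfg.feet_band_fraction)
        flat = ff.extract_foot_flat(afi, ordinal=ordinal)
        if flat is not None:
            flats.append(flat)
    ff.assign_foot_sides(
        flats,
        walking_direction=norm.walking_direction,
        camera_side=norm.camera_side,
    )
    sl_left, sl_right, sl_symm = ff.compute_step_lengths(flats)
    all_steps = sl_left + sl_right
    c = ff.compute_normalized_step_count(flats, all_steps)
    s = ff.compute_speed(all_steps, events.d)
    ffr_left, ffr_right = ff.compute_ffr_per_side(
        norm,
        flats,
        events,
        coverage_full=cfg.coverage_full,
        coverage_partial=cfg.coverage_partial,
    )

    # amount of movement over mid-delimited half cycles, attributed to the
    # side of the foot whose initial contact falls inside the half cycle
    side_of_ic = {flat.ic_frame: flat.side for flat in flats}
    aom = {"left": [], "right": []}
    for a, b in events.half_cycles_mid:
        ics_inside = [
            int(ic) for ic in events.initial_contacts if a <= ic < b
        ]
        side = next(
            (side_of_ic[ic] for ic in ics_inside if ic in side_of_ic), None
        )
        if side is None:
            logger.debug("half cycle [%d,%d) has no labelled contact; skipped", a, b)
            continue
        gei = bf.compute_gei(norm, (a, b), scope="half_cycle")
        gei.side = side
        aom[side].append(
            bf.compute_amount_of_movement(gei, levels=cfg.quantization_levels)
        )
    if not aom["left"] or not aom["right"]:
        raise InsufficientStepsError("no amount-of-movement value on one side")
    aom_left = float(median(aom["left"]))
    aom_right = float(median(aom["right"]))
    aom_symm = bf.compute_aom_symmetry(aom["left"], aom["right"])

    # full-cycle GEI features, median across cycles
    cog_shifts, torso_angles = [], []
    for interval in events.full_cycles():
        gei_full = bf.compute_gei(norm, interval, scope="full_cycle")
        cog_shifts.append(
            bf.compute_cog_shift(gei_full, feet_fraction=cfg.feet_band_fraction).shift
        )
        torso_angles.append(
            bf.compute_torso_orientation(
                gei_full,
                top_fraction=cfg.torso_top_fraction,
                bottom_fraction=cfg.torso_bottom_fraction,
            )
        )
    return {
        "SL_left": float(median(sl_left)),
        "SL_right": float(median(sl_right)),
        "SL_symm": sl_symm,
        "FFR_left": ffr_left,
        "FFR_right": ffr_right,
        "S": s,
        "C": c,
        "TO": float(median(torso_angles)),
        "COG_shift": float(median(cog_shifts)),
        "AOM_left": aom_left,
        "AOM_right": aom_right,
        "AOM_symm": aom_symm,
    }


def extract_feature_table(
    entries,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Feature table for an iterable of (sequence, label, subject_id).

    Accepts ``(seq, label, subject_id)`` triples or objects with
    ``sequence`` / ``label`` / ``subject_id`` attributes (cohort entries).
    """
    rows = []
    for entry in entries:
        if hasattr(entry, "sequence"):
            seq, label, subject = entry.sequence, entry.label, entry.subject_id
        else:
            seq, label, subject = entry
        feats = extract_features(seq, config=config)
        feats["label"] = label
        feats["subject_id"] = subject
        rows.append(feats)
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label", "subject_id"])
    bad = table[list(FEATURE_COLUMNS)].apply(
        lambda c: ~np.isfinite(c.astype(float))
    )
    if bad.to_numpy().any():
        raise InsufficientStepsError("non-finite feature values in table")
    return table
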