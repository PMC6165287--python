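"""Foot-flat extraction and the feet-related biomechanical features."""

from __future__ import annotations

import warnings
from dataclasses import replace
from statistics import median

import numpy as np
import pytest

import gaitsil as gs
from gaitsil.cycles import GaitEvents
from gaitsil.errors import (
    DegenerateInputError,
    InsufficientStepsError,
    NoFootFlatWarning,
)
from gaitsil.feet_features import AverageFeetImage, FootFlat
from gaitsil.synthetic_walker import _BASE_PRESETS

from conftest import make_sequence


def afi_from(grid, row_offset=180, T=10):
    grid = np.asarray(grid, dtype=float)
    return AverageFeetImage(grid=grid, T=T, interval=(0, T), row_offset=row_offset)


def flat_at(x, y, ordinal=0, side=None, ic_frame=0):
    mask = np.ones((2, 2), dtype=bool)
    return FootFlat(
        mask=mask, centroid=(float(x), float(y)), ordinal=ordinal,
        interval=(0, 1), row_offset=0, ic_frame=ic_frame, side=side,
    )


class TestAFI:
    def test_mean_of_identical_crops_is_the_crop(self, nm_walker):
        seq, _ = nm_walker
        static = make_sequence(np.repeat(seq.frames[:1], 6, axis=0))
        afi = gs.compute_afi(static, (0, 6))
        band = static.frames[0][afi.row_offset :, :]
        np.testing.assert_array_equal(afi.grid, band.astype(float))

    def test_disjoint_masks_average_to_half(self):
        frames = np.zeros((2, 20, 30), dtype=np.uint8)
        frames[0, -2:, 2:8] = 1
        frames[1, -2:, 12:18] = 1
        afi = gs.compute_afi(make_sequence(frames), (0, 2))
        occupied = afi.grid[afi.grid > 0]
        np.testing.assert_allclose(occupied, 0.5)

    def test_band_is_bottom_tenth(self):
        frames = np.ones((2, 200, 10), dtype=np.uint8)
        afi = gs.compute_afi(make_sequence(frames), (0, 2))
        assert afi.grid.shape[0] == 20
        assert afi.row_offset == 180

    def test_empty_interval_rejected(self, nm_walker):
        seq, _ = nm_walker
        with pytest.raises(DegenerateInputError):
            gs.compute_afi(seq, (10, 10))


class TestOtsuFootFlat:
    def test_bimodal_afi_isolates_bright_mode(self):
        grid = np.zeros((10, 20))
        grid[:5, :10] = 0.2
        grid[5:, 10:] = 0.9
        thresh = gs.otsu_threshold_nonzero(grid)
        assert 0.2 < thresh <= 0.9
        flat = gs.extract_foot_flat(afi_from(grid))
        ys, xs = np.nonzero(flat.mask)
        assert ys.min() >= 5 and xs.min() >= 10

    def test_otsu_matches_exhaustive_variance_maximizer(self):
        """The threshold achieves the exhaustive-search maximum of the
        between-class variance on the 256-bin histogram of nonzero values."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            T = int(rng.integers(5, 40))
            vals = rng.integers(1, T + 1, size=int(rng.integers(60, 400))) / T
            if vals.max() == vals.min():
                continue
            thresh = gs.otsu_threshold_nonzero(vals.reshape(1, -1))
            hist, edges = np.histogram(vals, bins=256)
            centers = (edges[:-1] + edges[1:]) / 2
            total = hist.sum()
            best = -1.0
            achieved = None
            for cut in range(1, 256):
                w0 = hist[:cut].sum()
                w1 = total - w0
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (hist[:cut] * centers[:cut]).sum() / w0
                mu1 = (hist[cut:] * centers[cut:]).sum() / w1
                var = w0 * w1 * (mu0 - mu1) ** 2
                best = max(best, var)
                if np.isclose(centers[cut - 1], thresh):
                    achieved = var
            assert achieved is not None
            assert achieved >= best * (1 - 1e-12)

    def test_uniform_afi_skipped_with_warning(self):
        with pytest.warns(NoFootFlatWarning):
            assert gs.extract_foot_flat(afi_from(np.full((5, 5), 0.7))) is None

    def test_all_zero_afi_skipped(self):
        with pytest.warns(NoFootFlatWarning):
            assert gs.extract_foot_flat(afi_from(np.zeros((5, 5)))) is None

    def test_largest_component_kept(self):
        grid = np.zeros((10, 30))
        grid[2:4, 2:5] = 0.9       # 6 px blob
        grid[5:9, 10:20] = 0.95    # 40 px blob
        grid[0, 29] = 0.1
        flat = gs.extract_foot_flat(afi_from(grid))
        assert flat.mask.sum() == 40

    def test_footprint_iou_against_ground_truth(self, nm_walker):
        """Extracted footprints overlap the commanded stance rectangles."""
        seq, truth = nm_walker
        ics = truth.contact_frames
        ious = []
        for i in range(len(ics) - 1):
            afi = gs.compute_afi(seq, (int(ics[i]), int(ics[i + 1])))
            flat = gs.extract_foot_flat(afi, ordinal=i)
            assert flat is not None
            x0, x1, y0, y1 = truth.footprints[i]
            truth_mask = np.zeros(seq.frame_shape, dtype=bool)
            truth_mask[y0 : y1 + 1, x0 : x1 + 1] = True
            got = flat.full_frame_mask(seq.frame_shape)
            inter = (truth_mask & got).sum()
            union = (truth_mask | got).sum()
            ious.append(inter / union)
        assert min(ious) >= 0.7


class TestSideAssignment:
    def test_elevated_centroid_is_far_foot(self):
        flats = [flat_at(100, 195), flat_at(180, 190)]
        gs.assign_foot_sides(flats, camera_side="right")
        assert flats[0].side == "right"  # lower centroid = near = camera side
        assert flats[1].side == "left"

    def test_camera_side_left_mapping(self):
        flats = [flat_at(100, 195), flat_at(180, 190)]
        gs.assign_foot_sides(flats, camera_side="left")
        assert [f.side for f in flats] == ["left", "right"]

    def test_tied_pair_skipped_parity_from_rest(self):
        flats = [flat_at(0, 190), flat_at(50, 190), flat_at(100, 195)]
        gs.assign_foot_sides(flats, camera_side="right")
        # informative pair: flat1 (y=190) far vs flat2 (y=195) near
        assert flats[1].side == "left"
        assert flats[2].side == "right"
        assert flats[0].side == "right"  # alternation

    def test_sides_alternate(self):
        flats = [flat_at(60 * i, 195 if i % 2 == 0 else 190) for i in range(6)]
        gs.assign_foot_sides(flats, camera_side="right")
        sides = [f.side for f in flats]
        assert sides == ["right", "left"] * 3

    def test_walker_sides_match_ground_truth(self, nm_walker):
        seq, truth = nm_walker
        ics = truth.contact_frames
        flats = []
        for i in range(len(ics) - 1):
            flat = gs.extract_foot_flat(
                gs.compute_afi(seq, (int(ics[i]), int(ics[i + 1]))), ordinal=i
            )
            flats.append(flat)
        gs.assign_foot_sides(flats, camera_side=seq.camera_side)
        assert [f.side for f in flats] == truth.contact_sides[:-1]

    def test_too_few_flats_rejected(self):
        with pytest.raises(InsufficientStepsError):
            gs.assign_foot_sides([flat_at(0, 0)])


class TestStepLengths:
    def test_euclidean_distance(self):
        flats = [
            flat_at(100, 200, side="left"),
            flat_at(180, 200, side="right"),
            flat_at(290, 200, side="left"),
        ]
        sl_l, sl_r, _ = gs.compute_step_lengths(flats)
        assert sl_r == [pytest.approx(80.0)]
        assert sl_l == [pytest.approx(110.0)]

    def test_symmetry_score_from_side_medians(self):
        # gaps chosen so median(left)=115.16 and median(right)=63.24
        xs = np.cumsum([0, 63.24, 115.16, 63.24, 115.16])
        sides = ["left", "right", "left", "right", "left"]
        flats = [flat_at(x, 195, side=s) for x, s in zip(xs, sides)]
        _, _, symm = gs.compute_step_lengths(flats)
        assert symm == pytest.approx(51.92)

    def test_symmetric_walker_symmetry_small(self, nm_features):
        assert nm_features["SL_symm"] <= 2.0
        assert abs(nm_features["SL_left"] - nm_features["SL_right"]) <= 2.0

    def test_step_side_is_arriving_foot(self):
        flats = [
            flat_at(0, 195, side="left"),
            flat_at(70, 190, side="right"),
            flat_at(170, 195, side="left"),
        ]
        sl_l, sl_r, _ = gs.compute_step_lengths(flats)
        assert sl_r == [pytest.approx(np.hypot(70, 5))]
        assert sl_l == [pytest.approx(np.hypot(100, 5))]

    def test_one_side_missing_rejected(self):
        flats = [flat_at(0, 195, side="left"), flat_at(70, 195, side="left")]
        with pytest.raises(InsufficientStepsError, match="insufficient steps"):
            gs.compute_step_lengths(flats)

    def test_monotone_in_commanded_step_length(self):
        """Longer commanded steps measure as longer median step lengths."""
        meas = []
        for sl in (80.0, 110.0):
            params = replace(
                _BASE_PRESETS["NM"], step_length_left=sl, step_length_right=sl
            )
            seq, _ = gs.generate_walker(params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                feats = gs.extract_features(seq)
            meas.append(median([feats["SL_left"], feats["SL_right"]]))
        assert meas[1] > meas[0]


class TestCountsSpeed:
    def test_normalized_step_count(self):
        assert gs.compute_normalized_step_count(4, [100.0] * 4) == pytest.approx(0.01)

    def test_halving_steps_doubles_count(self):
        c1 = gs.compute_normalized_step_count(5, [100.0] * 4)
        c2 = gs.compute_normalized_step_count(5, [50.0] * 4)
        assert c2 == pytest.approx(2 * c1)

    def test_zero_distance_rejected(self):
        with pytest.raises(DegenerateInputError):
            gs.compute_normalized_step_count(2, [0.0])

    def test_nm_preset_step_count_near_benchmark(self, nm_features):
        """The normal-gait preset lands near 0.010 steps/px."""
        assert nm_features["C"] == pytest.approx(0.010, rel=0.20)

    def test_speed(self):
        assert gs.compute_speed([100.0] * 4, 5.0) == pytest.approx(80.0)

    def test_speed_unit_law(self):
        steps = [90.0, 110.0]
        assert gs.compute_speed(steps, 2.0) == pytest.approx(
            2 * gs.compute_speed(steps, 4.0)
        )

    def test_zero_duration_rejected(self):
        with pytest.raises(DegenerateInputError):
            gs.compute_speed([100.0], 0.0)

    def test_fb_slower_than_nm(self, fb_features, nm_features):
        assert fb_features["S"] < nm_features["S"]

    def test_conservation_steps_vs_flats(self, nm_features, nm_walker):
        seq, truth = nm_walker
        norm = gs.normalize_height(seq, 200)
        sig = gs.compute_feet_distance_signal(norm)
        ev = gs.detect_gait_events(sig)
        flats = [
            gs.extract_foot_flat(gs.compute_afi(norm, iv), ordinal=i)
            for i, iv in enumerate(ev.half_cycles_ic)
        ]
        flats = [f for f in flats if f is not None]
        gs.assign_foot_sides(flats, camera_side=seq.camera_side)
        sl_l, sl_r, _ = gs.compute_step_lengths(flats)
        assert len(sl_l) + len(sl_r) == len(flats) - 1


class TestFootFlatRatio:
    def _coverage_setup(self):
        frames = np.zeros((22, 24, 30), dtype=np.uint8)
        frames[:, 2, 2] = 1  # keep frames nonempty
        frames[:16, 19:24, 5:15] = 1          # fully covered 16 frames
        frames[16:20, 19:24, 5:11] = 1        # 60% covered 4 frames
        mask = np.zeros((5, 30), dtype=bool)
        mask[:, 5:15] = True
        flat = FootFlat(
            mask=mask, centroid=(9.5, 21.0), ordinal=0,
            interval=(0, 10), row_offset=19, ic_frame=0, side="left",
        )
        events = GaitEvents(
            initial_contacts=np.array([0, 10, 21]),
            midpoints=np.array([5, 15]),
            fps=30.0,
        )
        return make_sequence(frames), flat, events

    def test_flat_over_stance_ratio(self):
        seq, flat, events = self._coverage_setup()
        ffr = gs.compute_foot_flat_ratio(seq, flat, events)
        assert ffr == pytest.approx(16 / 20)

    def test_never_negative_and_clipped(self):
        seq, flat, events = self._coverage_setup()
        ffr = gs.compute_foot_flat_ratio(
            seq, flat, events, coverage_full=0.99, coverage_partial=0.5
        )
        assert 0.0 <= ffr <= 1.0

    def test_commanded_flat_fraction_recovered(self, nm_walker, nm_features):
        _, truth = nm_walker
        for side in ("FFR_left", "FFR_right"):
            assert abs(nm_features[side] - truth.flat_fraction) <= 0.1


class TestTranslationInvariance:
    def test_horizontal_shift_leaves_steps_unchanged(self, nm_walker, nm_features):
        seq, _ = nm_walker
        pad = np.zeros((seq.n_frames, seq.frames.shape[1], 25), dtype=np.uint8)
        shifted = make_sequence(
            np.concatenate([pad, seq.frames], axis=2),
            camera_side=seq.camera_side,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = gs.extract_features(shifted)
        # sub-pixel rasterization rounding is the only admissible difference
        for key in ("SL_left", "SL_right", "SL_symm"):
            assert feats[key] == pytest.approx(nm_features[key], abs=0.5)
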