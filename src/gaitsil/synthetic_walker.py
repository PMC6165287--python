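"""Synthetic lateral-view walker: binary silhouettes with ground truth.

Renders an articulated 2-D stick body — head ellipse, leanable torso,
two-segment legs and flat rectangular feet — walking across the frame. Feet
follow an explicit contact schedule: a foot plants at its commanded contact
position, stays flat-footed for a commanded fraction of its stance phase,
rolls over the toe, and swings to its next contact along a smooth lifted
trajectory. All the silhouette phenomena the analysis pipeline consumes are
therefore controllable and recorded as ground truth: per-side step lengths,
cadence (hence speed), torso lean, per-side movement restriction (swing lift
and knee flexion scaling) and the flat-foot dwell fraction.

Class presets emulate four gait groups: normal (NM), full-body restriction
with short steps, hunched posture and slow cadence (FB, parkinsonian-like),
and single-side restrictions (RL/LL, hemiplegic-like).

Kinematics are schematic (smoothstep swing, linear roll-over), not
biomechanically validated; only the induced silhouette phenomena — width
periodicity, foot dwell, lean, limb excursion — need to be faithful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .errors import GaitSilError
from .io_preproc import SilhouetteSequence

CLASS_LABELS = ("FB", "RL", "LL", "NM")

# body geometry in px, scaled to a 200 px standing silhouette
_LEG_LEN = 100.0      # hip height above ground
_TORSO_LEN = 66.0     # hip to neck
_NECK_LEN = 13.0
_HEAD_RY = 20.0       # head vertical radius
_HEAD_RX = 14.0
_TORSO_W = 36.0
_THIGH_W = 16.0
_SHANK_W = 11.0
_FOOT_LEN = 30.0
_FOOT_H = 10.0
_FAR_EXTRA_H = 6.0    # far foot drawn taller: its centroid sits higher, the
                      # elevation cue a lateral view shows, while both feet
                      # share one ground line (stable silhouette baseline)
_LIFT_HEIGHT = 26.0   # swing-foot apex at movement scale 1
_KNEE_BOW = 26.0      # peak forward knee-flexion bow during swing
_HEEL_MAX = math.radians(20.0)  # heel-off roll reached at the lift instant
_TUCK_MAX = math.radians(50.0)  # extra plantar-flexion at mid-swing
_STANCE_FRAC = 0.6    # stance = 60% of the gait cycle (two step periods)


@dataclass(frozen=True)
class WalkerParams:
    """Controls of the synthetic walker (deterministic given the fields)."""

    step_length_left: float = 100.0
    step_length_right: float = 100.0
    cadence: float = 0.9            # steps per second
    torso_lean: float = 0.0         # degrees from vertical, forward positive
    movement_scale_left: float = 1.0
    movement_scale_right: float = 1.0
    flat_fraction: float = 0.6      # fraction of stance spent flat-footed
    n_steps: int = 6
    fps: float = 30.0
    frame_height: int = 220
    frame_width: int | None = None  # None = auto-size to the travelled span
    camera_side: str = "right"      # body side facing the camera
    noise: float = 0.0              # per-pixel flip probability
    seed: int = 0

    def validate(self) -> None:
        if min(self.step_length_left, self.step_length_right) <= 0:
            raise GaitSilError("step lengths must be > 0")
        if self.cadence <= 0:
            raise GaitSilError("cadence must be > 0")
        for s in (self.movement_scale_left, self.movement_scale_right):
            if not 0 < s <= 1:
                raise GaitSilError("movement scales must be in (0, 1]")
        if not 0 < self.flat_fraction <= 1:
            raise GaitSilError("flat_fraction must be in (0, 1]")
        if self.n_steps < 2:
            raise GaitSilError("n_steps must be >= 2")
        if self.fps <= 0:
            raise GaitSilError("fps must be > 0")
        if self.camera_side not in ("left", "right"):
            raise GaitSilError("camera_side must be 'left' or 'right'")


@dataclass(eq=False)
class GroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    contact_frames: np.ndarray          # frame index of each initial contact
    contact_sides: list[str]            # alternating left/right
    contact_positions: np.ndarray       # footprint center x at each contact
    step_lengths: list[tuple[str, float]]  # (side of arriving foot, px)
    flat_intervals: list[tuple[int, int]]  # commanded flat-foot frame spans
    footprints: list[tuple[int, int, int, int]]  # (x0, x1, y0, y1) inclusive
    commanded_speed: float              # px/s over the executed steps
    step_period_frames: float
    torso_lean: float
    flat_fraction: float
    label: str | None
    params: WalkerParams

    def step_lengths_side(self, side: str) -> list[float]:
        return [l for s, l in self.step_lengths if s == side]


class _FootPose(NamedTuple):
    x: float          # footprint center x
    lift: float       # bottom elevation above the foot's ground line
    heel_angle: float # roll about the toe, radians
    planted: bool


def _smoothstep(u: float) -> float:
    return u * u * (3.0 - 2.0 * u)


def _foot_pose(
    t: float,
    contacts: list[tuple[float, float]],
    stance_T: float,
    flat_fraction: float,
    lift_height: float,
    arc_fraction: float = 1.0,
) -> _FootPose:
    """Pose of one foot given its own (time, position) contact schedule."""
    idx = None
    for j, (tc, _) in enumerate(contacts):
        if t >= tc:
            idx = j
    if idx is None:  # before this foot's first scheduled contact: hold it
        return _FootPose(contacts[0][1], 0.0, 0.0, True)
    tc, xc = contacts[idx]
    lift_time = tc + stance_T
    flat_end = tc + flat_fraction * stance_T
    has_next = idx + 1 < len(contacts)
    if t <= lift_time or not has_next:
        if t <= flat_end:
            return _FootPose(xc, 0.0, 0.0, True)
        phase = (t - flat_end) / (lift_time - flat_end)
        # slow linear roll about the toe: full sole contact ends right at the
        # commanded flat end, while the toe stays grounded until lift
        return _FootPose(xc, 0.0, _HEEL_MAX * min(1.0, phase), True)
    t_next, x_next = contacts[idx + 1]
    u = (t - lift_time) / (t_next - lift_time)
    u = min(1.0, max(0.0, u))
    x = xc + (x_next - xc) * _smoothstep(u)
    if u < arc_fraction:
        v = u / arc_fraction
        # plantar-flexed "tuck" keeps the airborne foot compact mid-swing and
        # drops it flat by the end of the arc; continuous with the stance roll
        angle = (_HEEL_MAX + _TUCK_MAX * math.sin(math.pi * v)) * (1.0 - v**3)
        # back-loaded arc: the excursion peaks late, so a leg's richest motion
        # falls inside the half cycle in which that foot lands
        arc = v * v * math.sin(math.pi * v) / 0.40
        return _FootPose(x, lift_height * arc, angle, False)
    # restricted-side shuffle: after a compressed arc the foot glides to its
    # contact just above the ground, a hesitant low-clearance landing
    w = (u - arc_fraction) / max(1e-9, 1.0 - arc_fraction)
    return _FootPose(x, 1.5 * (1.0 - w * w), 0.0, False)


def _fill_polygon(canvas: np.ndarray, xs, ys) -> None:
    rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=canvas.shape)
    canvas[rr, cc] = 1


def _thick_line(canvas: np.ndarray, p0, p1, width: float) -> None:
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    length = math.hypot(dx, dy)
    if length < 1e-9:
        return
    nx = -dy / length * width / 2
    ny = dx / length * width / 2
    _fill_polygon(
        canvas,
        [x0 + nx, x1 + nx, x1 - nx, x0 - nx],
        [y0 + ny, y1 + ny, y1 - ny, y0 - ny],
    )


def _foot_polygon(
    pose: _FootPose, ground: float, s: float, foot_h: float = _FOOT_H
) -> tuple[list[float], list[float], tuple[float, float]]:
    """Foot quad and ankle point; rolls about the toe during heel-off."""
    hl = _FOOT_LEN / 2
    pivot_x = pose.x + hl * s
    pivot_y = ground - pose.lift
    rel = [(-_FOOT_LEN * s, 0.0), (-_FOOT_LEN * s, -foot_h), (0.0, -foot_h), (0.0, 0.0)]
    a = pose.heel_angle * s
    ca, sa = math.cos(a), math.sin(a)
    xs, ys = [], []
    for rx, ry in rel:
        xs.append(pivot_x + rx * ca - ry * sa)
        ys.append(pivot_y + rx * sa + ry * ca)
    # leg joins the foot above its center: keeps the in-band shank strip from
    # biasing the footprint centroid along the walking direction
    ax, ay = -0.5 * _FOOT_LEN * s, -foot_h
    ankle = (pivot_x + ax * ca - ay * sa, pivot_y + ax * sa + ay * ca)
    return xs, ys, ankle


def generate_walker(
    params: WalkerParams,
    label: str | None = None,
) -> tuple[SilhouetteSequence, GroundTruth]:
    """Render the walker and return the sequence plus its ground truth.

    The walker advances rightward; contacts alternate starting with the left
    foot. The foot on the ``camera_side`` of the body is drawn on the lower
    ground line; the far foot's ground line sits a few pixels higher, the
    elevation cue real lateral views show.
    """
    params.validate()
    sl = {"left": params.step_length_left, "right": params.step_length_right}
    mscale = {
        "left": params.movement_scale_left,
        "right": params.movement_scale_right,
    }
    n = params.n_steps
    t_step = 1.0 / params.cadence
    stance_T = _STANCE_FRAC * 2.0 * t_step
    side_of = lambda i: "left" if i % 2 == 0 else "right"  # noqa: E731

    # contact positions, including two virtual contacts before frame 0
    x0 = sl[side_of(-1)] + sl[side_of(0)] + _FOOT_LEN + 40.0
    pos: dict[int, float] = {-2: x0 - sl[side_of(-1)] - sl[side_of(0)],
                             -1: x0 - sl[side_of(0)]}
    pos[0] = x0
    for i in range(1, n):
        pos[i] = pos[i - 1] + sl[side_of(i)]
    # virtual closing contact: after the last commanded step the trailing
    # foot swings up next to the leading one, so the pass ends feet-together
    # and the final width maximum is a genuine local peak
    pos[n] = pos[n - 1] - _FOOT_LEN * 0.8

    t_start = -0.4 * t_step
    t_end = (n - 1) * t_step + 0.4 * t_step
    n_frames = int(round((t_end - t_start) * params.fps)) + 1

    width = params.frame_width or int(math.ceil(pos[n - 1] + _FOOT_LEN + 40))
    height = params.frame_height
    ground_near = height - 8.0
    head_top = ground_near - (_LEG_LEN + (_TORSO_LEN + _NECK_LEN + _HEAD_RY))
    if head_top < 2 or width < pos[n - 1] + _FOOT_LEN / 2 + 2 or pos[-2] < _FOOT_LEN:
        raise GaitSilError("frame too small for the commanded walk")

    near_side = params.camera_side
    foot_h_of = {
        side: _FOOT_H if side == near_side else _FOOT_H + _FAR_EXTRA_H
        for side in ("left", "right")
    }
    # per-foot contact schedules (time, position), incl. virtual lead-in and
    # closing contacts
    schedule = {
        side: [
            (i * t_step, pos[i])
            for i in range(-2, n + 1)
            if side_of(i) == side
        ]
        for side in ("left", "right")
    }
    hip_knots_t = np.array([i * t_step for i in range(-1, n + 1)])
    hip_knots_x = np.array([(pos[i] + pos[i - 1]) / 2 for i in range(-1, n + 1)])

    frames = np.zeros((n_frames, height, width), dtype=np.uint8)
    for f in range(n_frames):
        t = t_start + f / params.fps
        canvas = frames[f]
        hip_x = float(np.interp(t, hip_knots_t, hip_knots_x))
        hip = (hip_x, ground_near - _LEG_LEN)
        lean = math.radians(params.torso_lean)
        torso_dx, torso_dy = math.sin(lean), -math.cos(lean)
        for side in ("left", "right"):
            pose = _foot_pose(
                t,
                schedule[side],
                stance_T,
                params.flat_fraction,
                _LIFT_HEIGHT * mscale[side],
                arc_fraction=min(1.0, 0.4 + 0.6 * mscale[side]),
            )
            xs, ys, ankle = _foot_polygon(
                pose, ground_near, s=1.0, foot_h=foot_h_of[side]
            )
            _fill_polygon(canvas, xs, ys)
            # two-segment leg with a forward knee bow; swing flexion scales
            # with the side's movement restriction
            bend = 4.0
            if not pose.planted:
                swing_u = pose.lift / max(_LIFT_HEIGHT * mscale[side], 1e-9)
                bend += _KNEE_BOW * swing_u * mscale[side]
            knee = (
                (hip[0] + ankle[0]) / 2 + bend,
                (hip[1] + ankle[1]) / 2,
            )
            _thick_line(canvas, hip, knee, _THIGH_W)
            _thick_line(canvas, knee, ankle, _SHANK_W)
        neck = (hip[0] + _TORSO_LEN * torso_dx, hip[1] + _TORSO_LEN * torso_dy)
        _thick_line(canvas, hip, neck, _TORSO_W)
        head_c = (
            hip[0] + (_TORSO_LEN + _NECK_LEN) * torso_dx,
            hip[1] + (_TORSO_LEN + _NECK_LEN) * torso_dy,
        )
        _thick_line(canvas, hip, head_c, _SHANK_W)  # neck column
        rr, cc = draw_ellipse(
            head_c[1], head_c[0], _HEAD_RY, _HEAD_RX, shape=canvas.shape
        )
        canvas[rr, cc] = 1

    if params.noise > 0:
        rng = np.random.default_rng(params.seed)
        flips = rng.random(frames.shape) < params.noise
        frames = np.where(flips, 1 - frames, frames).astype(np.uint8)

    frame_of = lambda t: int(round((t - t_start) * params.fps))  # noqa: E731
    contact_frames = np.array([frame_of(i * t_step) for i in range(n)])
    contact_sides = [side_of(i) for i in range(n)]
    steps = [
        (side_of(i + 1), abs(pos[i + 1] - pos[i])) for i in range(n - 1)
    ]
    flat_intervals = [
        (
            frame_of(i * t_step),
            frame_of(i * t_step + params.flat_fraction * stance_T),
        )
        for i in range(n)
    ]
    footprints = []
    for i in range(n):
        fh = foot_h_of[side_of(i)]
        footprints.append(
            (
                int(round(pos[i] - _FOOT_LEN / 2)),
                int(round(pos[i] + _FOOT_LEN / 2)),
                int(round(ground_near - fh)),
                int(round(ground_near)),
            )
        )
    commanded_speed = (pos[n - 1] - pos[0]) / ((n - 1) * t_step)
    seq = SilhouetteSequence(
        frames,
        fps=params.fps,
        camera_side=params.camera_side,
        walking_direction="rightward",
    )
    truth = GroundTruth(
        contact_frames=contact_frames,
        contact_sides=contact_sides,
        contact_positions=np.array([pos[i] for i in range(n)]),
        step_lengths=steps,
        flat_intervals=flat_intervals,
        footprints=footprints,
        commanded_speed=commanded_speed,
        step_period_frames=t_step * params.fps,
        torso_lean=params.torso_lean,
        flat_fraction=params.flat_fraction,
        label=label,
        params=params,
    )
    return seq, truth


_BASE_PRESETS: dict[str, WalkerParams] = {
    "NM": WalkerParams(
        step_length_left=108.0,
        step_length_right=108.0,
        cadence=0.9,
        torso_lean=0.0,
        movement_scale_left=1.0,
        movement_scale_right=1.0,
        flat_fraction=0.60,
    ),
    "FB": WalkerParams(
        step_length_left=40.0,
        step_length_right=40.0,
        cadence=0.75,
        torso_lean=25.0,
        movement_scale_left=0.5,
        movement_scale_right=0.5,
        flat_fraction=0.80,
    ),
    "RL": WalkerParams(
        step_length_left=100.0,
        step_length_right=55.0,
        cadence=0.85,
        torso_lean=0.0,
        movement_scale_left=1.0,
        movement_scale_right=0.55,
        flat_fraction=0.65,
    ),
    "LL": WalkerParams(
        step_length_left=55.0,
        step_length_right=100.0,
        cadence=0.85,
        torso_lean=0.0,
        movement_scale_left=0.55,
        movement_scale_right=1.0,
        flat_fraction=0.65,
    ),
}


def preset_for_class(
    label: str,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.05,
) -> WalkerParams:
    """Class preset with seeded multiplicative "subject" jitter (sigma 5%).

    NM: equal, long steps, upright, unrestricted. FB: short equal steps,
    ~25 deg forward lean, both sides restricted, long flat dwell, slow
    cadence. RL/LL: one step length and that side's movement scale reduced.
    """
    if label not in _BASE_PRESETS:
        raise GaitSilError(f"unknown class label {label!r}")
    base = _BASE_PRESETS[label]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g = lambda: float(rng.normal(1.0, jitter))  # noqa: E731
    clip01 = lambda v: float(min(1.0, max(0.05, v)))  # noqa: E731
    return replace(
        base,
        step_length_left=base.step_length_left * g(),
        step_length_right=base.step_length_right * g(),
        cadence=base.cadence * g(),
        torso_lean=base.torso_lean + float(rng.normal(0.0, 1.5)),
        movement_scale_left=clip01(base.movement_scale_left * g()),
        movement_scale_right=clip01(base.movement_scale_right * g()),
        flat_fraction=clip01(base.flat_fraction * g()),
    )


class CohortEntry(NamedTuple):
    sequence: SilhouetteSequence
    truth: GroundTruth
    label: str
    subject_id: str


def generate_cohort(
    n_subjects: int = 10,
    sequences_per_subject: int = 2,
    labels: tuple[str, ...] = CLASS_LABELS,
    seed: int = 0,
) -> list[CohortEntry]:
    """Cohort of synthetic walkers: every subject walks every class.

    Subject variability is seeded 5% multiplicative jitter on the class
    preset, shared by that subject's recordings; each repeat adds a smaller
    2% within-subject jitter, mirroring repeated recordings of one person.
    """
    entries = []
    for ci, label in enumerate(labels):
        for subj in range(n_subjects):
            subject_rng = np.random.default_rng(
                np.random.SeedSequence([seed, ci, subj])
            )
            subject_params = preset_for_class(label, seed=subject_rng)
            for rep in range(sequences_per_subject):
                rep_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, ci, subj, rep])
                )
                p = subject_params
                p = replace(
                    p,
                    step_length_left=p.step_length_left
                    * float(rep_rng.normal(1.0, 0.02)),
                    step_length_right=p.step_length_right
                    * float(rep_rng.normal(1.0, 0.02)),
                    cadence=p.cadence * float(rep_rng.normal(1.0, 0.02)),
                )
                seq, truth = generate_walker(p, label=label)
                entries.append(
                    CohortEntry(seq, truth, label, f"S{subj:02d}")
                )
    return entries
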