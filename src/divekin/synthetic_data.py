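"""Synthetic dive generation: ground-truth 3D motion, camera rigs, rendering.

The generator builds a kinematically plausible 25-landmark lateral dive with
the structure the analysis assumes:

* a standing phase with the heels apart at ``stance_ratio`` x leg length;
* a frontal step of ``step_length`` by the foot ipsilateral to the dive,
  landing so the heel-to-heel distance in the preparatory posture stays at
  the stance target;
* a whole-body horizontal speed profile (smooth sin^4 ramp with a sharp,
  well-localized peak) rising to ``peak_speed`` over ``impulse_duration``
  along the ``departure_angle`` direction, then decaying;
* a knee flexion dip driven by a pelvis crouch sized so the planted-leg
  interior knee angle reaches ``knee_min_angle`` at ``flexion_timing`` of
  the impulse, followed by extension;
* final departure timed so the peak-velocity frame falls five frames after
  the last ipsilateral ground contact (inside the 6-frame lookahead rule).

Because the centre of mass aggregates planted and moving segments, the raw
construction would undershoot the speed and bias the departure direction
slightly; a small fixed-point calibration (a handful of deterministic
rebuilds) scales the speed profile and rotates the heading until the
measured peak resultant velocity and departure angle match the requested
targets.  Ground truth is then obtained by applying the variable definitions
to the noiseless trajectory itself, so it is self-consistent by
construction; the rendering/reconstruction/filtering chain is what the
downstream comparison actually exercises.

``render_views`` projects the trajectory through DLT cameras and adds
i.i.d. Gaussian pixel noise and confidence-zero dropouts, yielding the same
per-camera keypoint streams the readers ingest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body_model import CMTrajectory, Trajectory3D, whole_body_cm
from .calibration import ControlPointSet, DLTCamera, calibrate_dlt
from .dive_events import detect_foot_events, find_prv
from .dive_variables import DiveVariables, compute_dive_variables
from .errors import SpecError
from .pose_io import PoseSequence

__all__ = [
    "SyntheticDiveSpec",
    "GroundTruth",
    "generate_dive_3d",
    "make_camera_rig",
    "render_views",
    "generate_cohort_variables",
    "generate_cohort_specs",
    "MIRROR_MAP",
]

# BODY_25 left<->right landmark swap used to mirror a dive.
MIRROR_MAP = np.arange(25)
for _l, _r in [(2, 5), (3, 6), (4, 7), (9, 12), (10, 13), (11, 14),
               (15, 16), (17, 18), (19, 22), (20, 23), (21, 24)]:
    MIRROR_MAP[_l], MIRROR_MAP[_r] = _r, _l

ANKLE_HEIGHT = 0.08
FOOT_LENGTH = 0.15
REF_HEIGHT = 1.80


@dataclass
class SyntheticDiveSpec:
    """Parameters of one synthetic dive; defaults follow the coached targets
    (75% stance width, frontal step, 18 deg departure) and field-typical
    magnitudes for youth goalkeepers."""

    side: str = "right"
    fs: float = 120.0
    duration: float = 2.0
    stance_ratio: float = 0.75
    step_length: float = 0.45
    departure_angle: float = 18.0
    knee_min_angle: float = 110.0
    flexion_timing: float = 0.45
    peak_speed: float = 3.3
    impulse_duration: float = 0.55
    leg_length: float = 0.88
    body_mass: float = 78.0
    height: float = 1.80
    noise_px: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    pre_dive_duration: float = 0.5
    step_duration: float = 0.25
    step_height: float = 0.14
    eps_detect: float = 0.03
    k_detect: int = 3

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise SpecError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("fs", "duration", "stance_ratio", "step_length", "peak_speed",
                     "impulse_duration", "leg_length", "body_mass", "height",
                     "pre_dive_duration", "step_duration", "step_height"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if not 0.0 <= self.departure_angle <= 90.0:
            raise SpecError("departure_angle must lie in [0, 90] degrees")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SpecError("dropout_rate must lie in [0, 1)")
        if not 0.0 < self.flexion_timing < 1.0:
            raise SpecError("flexion_timing must lie in (0, 1)")
        if not 30.0 <= self.knee_min_angle < 180.0:
            raise SpecError("knee_min_angle must lie in [30, 180) degrees")
        if self.pre_dive_duration + self.impulse_duration + 0.35 > self.duration:
            raise SpecError(
                "duration too short for pre-dive phase + impulse + follow-through"
            )
        if self.step_duration >= self.impulse_duration:
            raise SpecError("step_duration must be shorter than impulse_duration")
        if self.step_length >= self.stance_ratio * self.leg_length:
            raise SpecError(
                "step_length must be smaller than stance_ratio * leg_length "
                "for a reachable preparatory posture"
            )


@dataclass
class GroundTruth:
    """Event frames and true variable values of a generated dive."""

    side: str
    t_start: int
    t_last_contact: int
    t_final_contact_start: int
    t_final_off: int
    t_prv: int
    variables: DiveVariables
    cm: CMTrajectory = field(repr=False)
    trajectory: Trajectory3D = field(repr=False)


def _cos_blend(n_frames: int, lo: int, hi: int) -> np.ndarray:
    """0->1 half-cosine ramp over frames [lo, hi], clamped outside."""
    t = np.arange(n_frames, dtype=float)
    x = np.clip((t - lo) / max(hi - lo, 1), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _speed_displacement(tau: np.ndarray, peak: float, dur: float, decay: float) -> np.ndarray:
    """Path length of the smooth speed profile at times ``tau`` (s).

    The speed rises as ``peak * sin^4(pi tau / (2 dur))`` and decays as the
    mirrored ``cos^4``: zero slope at both ends of each phase, but with a
    peak sharp enough that its discrete-time location is robust to the
    filtering and measurement noise of the analysis chain.
    """

    def _int_sin4(x: np.ndarray) -> np.ndarray:
        return 3.0 * x / 8.0 - np.sin(2 * x) / 4.0 + np.sin(4 * x) / 32.0

    def _int_cos4(x: np.ndarray) -> np.ndarray:
        return 3.0 * x / 8.0 + np.sin(2 * x) / 4.0 + np.sin(4 * x) / 32.0

    s = np.zeros_like(tau)
    rise = (tau > 0) & (tau <= dur)
    s[rise] = peak * (2 * dur / np.pi) * _int_sin4(np.pi * tau[rise] / (2 * dur))
    s_rise_total = peak * (2 * dur / np.pi) * _int_sin4(np.asarray(np.pi / 2))
    after = tau > dur
    td = np.minimum(tau[after] - dur, decay)
    s[after] = s_rise_total + peak * (2 * decay / np.pi) * _int_cos4(
        np.pi * td / (2 * decay)
    )
    return s


def _ik_knee(hip: np.ndarray, ankle: np.ndarray, lt: float, ls: float) -> np.ndarray:
    """Two-link knee position given hip and ankle paths, forward (+X) bias.

    The hip-ankle distance is saturated smoothly (softplus) just below the
    anatomical reach before solving the triangle, and the solution is scaled
    back onto the true endpoints: near and beyond full reach the knee angle
    approaches extension smoothly while the segments take up a mild virtual
    elongation.  This keeps the knee trajectory band-limited (no corner at
    the extension lock), which the simplified skeleton trades against rigid
    segment lengths late in the push-off.
    """
    diff = ankle - hip
    dist = np.linalg.norm(diff, axis=1)
    dist = np.maximum(dist, 1e-9)
    e = diff / dist[:, None]
    reach = lt + ls
    beta = 60.0
    d_eff = reach - np.logaddexp(0.0, beta * (reach - dist)) / beta
    d_eff = np.maximum(d_eff, 0.2 * reach)
    a = (lt**2 + d_eff**2 - ls**2) / (2.0 * d_eff)
    hk = np.sqrt(np.maximum(lt**2 - a**2, 0.0))
    scale = dist / d_eff
    a = a * scale
    hk = hk * scale
    # forward bias direction orthogonal to the hip-ankle axis
    fwd = np.zeros_like(e)
    fwd[:, 0] = 1.0
    fwd = fwd - (np.einsum("tc,tc->t", fwd, e))[:, None] * e
    nf = np.linalg.norm(fwd, axis=1)
    fallback = nf < 1e-9
    if fallback.any():
        fwd[fallback] = [0.0, 1.0, 0.0]
        fwd[fallback] -= (np.einsum("tc,tc->t", fwd[fallback], e[fallback]))[:, None] * e[fallback]
        nf = np.linalg.norm(fwd, axis=1)
    fwd = fwd / nf[:, None]
    return hip + a[:, None] * e + hk[:, None] * fwd


def _rodrigues(axis: np.ndarray, angles: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rotate a fixed vector by per-frame angles about a fixed unit axis."""
    c = np.cos(angles)[:, None]
    s = np.sin(angles)[:, None]
    k = axis / np.linalg.norm(axis)
    cross = np.cross(np.broadcast_to(k, (angles.size, 3)), vec)
    dot = float(np.dot(k, vec))
    return vec[None, :] * c + cross * s + k[None, :] * dot * (1.0 - c)


def _first_sustained_crossing(z: np.ndarray, eps: float, k: int) -> int:
    """First frame where z > eps for >= k consecutive frames (-1 if none)."""
    above = z > eps
    run = 0
    for i, v in enumerate(above):
        run = run + 1 if v else 0
        if run >= k:
            return i - k + 1
    return -1


def _build_canonical(spec: SyntheticDiveSpec, speed_scale: float, heading_deg: float) -> np.ndarray:
    """Construct a right-side dive as a (n_frames, 25, 3) landmark array."""
    fs = spec.fs
    n = int(round(spec.duration * fs))
    sh = spec.height / REF_HEIGHT
    L = spec.leg_length
    lt = ls = (L - ANKLE_HEIGHT) / 2.0
    stance = spec.stance_ratio * L
    hip_half = 0.12 * sh
    theta_stand = math.radians(168.0)

    d_stand = math.sqrt(lt**2 + ls**2 - 2 * lt * ls * math.cos(theta_stand))
    heel_y = {"right": -stance / 2.0, "left": +stance / 2.0}
    ankle_xy0 = {s: np.array([0.04, heel_y[s]]) for s in ("right", "left")}
    h0 = math.hypot(0.04, abs(heel_y["right"]) - hip_half)
    vert0 = math.sqrt(max(d_stand**2 - h0**2, 0.01))
    z_hip_stand = ANKLE_HEIGHT + vert0

    # --- ipsilateral (right) foot step flight -------------------------------
    f_off1 = int(round(spec.pre_dive_duration * fs))
    n_fl = int(round(spec.step_duration * fs))
    f_land = f_off1 + n_fl
    t_frames = np.arange(n)

    flight = (t_frames >= f_off1) & (t_frames < f_land)
    z_step = np.zeros(n)
    z_step[flight] = spec.step_height * np.sin(
        np.pi * (t_frames[flight] - f_off1) / n_fl
    ) ** 2

    # horizontal swing finishes before touchdown so the preparatory posture
    # is already assembled when contact is detected
    a_lead = max(1, int(round(n_fl * 0.17)))
    b_trail = max(2, int(round(n_fl * 0.20)))
    swing = _cos_blend(n, f_off1 + a_lead, f_land - b_trail)
    lat_sep = math.sqrt((spec.stance_ratio * L) ** 2 - spec.step_length**2)
    y_land = heel_y["left"] - lat_sep  # measured from the contralateral heel
    heel_ipsi = np.zeros((n, 3))
    heel_ipsi[:, 0] = swing * spec.step_length
    heel_ipsi[:, 1] = heel_y["right"] + swing * (y_land - heel_y["right"])
    heel_ipsi[:, 2] = z_step

    # --- cycle anchors ------------------------------------------------------
    t_start = _first_sustained_crossing(z_step, spec.eps_detect, spec.k_detect)
    if t_start < 0:
        raise SpecError("step flight never clears the contact threshold")
    t_prv = t_start + int(round(spec.impulse_duration * fs))

    # --- whole-body horizontal path -----------------------------------------
    alpha = math.radians(heading_deg)
    heading = np.array([math.sin(alpha), -math.cos(alpha), 0.0])
    tau = (t_frames - t_start) / fs
    peak = spec.peak_speed * speed_scale
    s_path = _speed_displacement(tau, peak, spec.impulse_duration, 0.30)
    root_disp = s_path[:, None] * heading[None, :]

    # --- final departure of the ipsilateral foot ---------------------------
    # the foot's horizontal velocity ramps monotonically from rest to the
    # root velocity (no overshoot that would perturb the CM-speed peak),
    # while an independent half-cosine bell lifts it off the ground
    n_blend = int(round(0.30 * fs))
    lift_h = 0.35
    w_profile = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_blend + 1) / n_blend))
    delta2 = int(np.argmax(w_profile * lift_h > spec.eps_detect))
    # last contact lands 5 frames before the peak: inside the 6-frame
    # lookahead with margin for measurement noise around the flat peak
    f_off2 = t_prv - 4 - delta2
    if f_off2 <= f_land + spec.k_detect:
        raise SpecError("impulse_duration leaves no planted preparatory phase")

    def _lifted_track(
        planted: np.ndarray, f0: int, blend: int, lift: float, h_start: int
    ) -> np.ndarray:
        # vertical lift bell from f0; horizontal catch-up toward the root
        # velocity from h_start (a trailing foot lifts first, then follows)
        wz = _cos_blend(n, f0, f0 + blend)
        wh = _cos_blend(n, h_start, h_start + blend)
        d_root = np.diff(root_disp, axis=0, prepend=root_disp[:1])
        catchup = np.cumsum(wh[:, None] * d_root, axis=0)
        track = planted[None, :] + catchup - catchup[f0][None, :]
        track[:f0] = planted
        track[:, 2] = planted[2] + lift * wz
        return track

    planted = heel_ipsi[f_land - 1].copy()
    planted[2] = 0.0
    # horizontal catch-up only after the peak-velocity frame so the CM speed
    # maximum is governed by the root profile alone
    lifted = _lifted_track(planted, f_off2, n_blend, lift_h, t_prv + 2)
    after = t_frames >= f_land
    heel_ipsi[after] = lifted[after]

    # --- contralateral (left) foot ------------------------------------------
    # its catch-up completes before the peak-velocity frame so the CM speed
    # maximum stays where the root profile puts it
    f_coff = t_start + int(round(0.55 * spec.impulse_duration * fs))
    n_blend_c = min(n_blend, t_prv - 2 - f_coff)
    if n_blend_c < 4:
        raise SpecError("impulse_duration too short for the push-off leg lift")
    planted_c = np.array([0.0, heel_y["left"], 0.0])
    heel_contra = _lifted_track(planted_c, f_coff, n_blend_c, 0.30, f_coff)

    # --- pelvis crouch sized to the knee-angle target ------------------------
    t_dip = t_start + spec.flexion_timing * spec.impulse_duration * fs
    w_end = t_start + 0.9 * spec.impulse_duration * fs
    d_min = math.sqrt(
        lt**2 + ls**2 - 2 * lt * ls * math.cos(math.radians(spec.knee_min_angle))
    )
    i_dip = int(round(t_dip))
    hip_c_xy = root_disp[i_dip, :2] + np.array([0.0, hip_half])
    h_dip = float(np.linalg.norm(hip_c_xy - ankle_xy0["left"]))
    vert_target_sq = d_min**2 - h_dip**2
    if vert_target_sq < 0.01:
        warnings.warn(
            "knee_min_angle unreachable at the dip instant; crouch depth clamped",
            stacklevel=2,
        )
        vert_target_sq = 0.01
    dip_max = max(vert0 - math.sqrt(vert_target_sq), 0.0)
    dip = np.zeros(n)
    down = (t_frames >= t_start) & (t_frames <= t_dip)
    up = (t_frames > t_dip) & (t_frames <= w_end)
    dip[down] = dip_max * 0.5 * (1 - np.cos(np.pi * (t_frames[down] - t_start) / (t_dip - t_start)))
    dip[up] = dip_max * 0.5 * (1 + np.cos(np.pi * (t_frames[up] - t_dip) / (w_end - t_dip)))

    mid_hip = root_disp + np.array([0.0, 0.0, z_hip_stand])[None, :]
    mid_hip[:, 2] -= dip

    # --- trunk, head, arms with a lean toward the dive direction -------------
    lean_axis = np.array([-heading[1], heading[0], 0.0])
    lean = math.radians(20.0) * _cos_blend(
        n, t_start, t_start + int(round(0.8 * (t_prv - t_start)))
    )
    offsets = {
        1: (0.00, 0.00, 0.50),   # neck
        0: (0.10, 0.00, 0.60),   # nose
        15: (0.10, -0.035, 0.63), 16: (0.10, 0.035, 0.63),   # eyes
        17: (0.02, -0.07, 0.60), 18: (0.02, 0.07, 0.60),     # ears
        2: (0.00, -0.20, 0.44), 5: (0.00, 0.20, 0.44),       # shoulders
        3: (0.03, -0.29, 0.22), 6: (0.03, 0.29, 0.22),       # elbows
        4: (0.06, -0.32, 0.02), 7: (0.06, 0.32, 0.02),       # wrists
    }

    P = np.zeros((n, 25, 3))
    P[:, 8] = mid_hip
    for lid, off in offsets.items():
        vec = np.asarray(off) * sh
        P[:, lid] = mid_hip + _rodrigues(lean_axis, lean, vec)

    hip_r = mid_hip + np.array([0.0, -hip_half, 0.0])
    hip_l = mid_hip + np.array([0.0, +hip_half, 0.0])
    P[:, 9] = hip_r
    P[:, 12] = hip_l

    foot_pts = {
        "big_toe": np.array([FOOT_LENGTH, 0.0, 0.0]),
        "small_toe": np.array([FOOT_LENGTH - 0.02, 0.0, 0.0]),
        "ankle": np.array([0.04, 0.0, ANKLE_HEIGHT]),
    }
    for side_name, heel, hip, toe_y in (
        ("right", heel_ipsi, hip_r, -0.05),
        ("left", heel_contra, hip_l, +0.05),
    ):
        ids = {"right": (22, 23, 24, 11, 10), "left": (19, 20, 21, 14, 13)}[side_name]
        big_toe, small_toe, heel_id, ankle_id, knee_id = ids
        P[:, heel_id] = heel
        P[:, big_toe] = heel + foot_pts["big_toe"]
        P[:, small_toe] = heel + foot_pts["small_toe"] + np.array([0.0, toe_y, 0.0])
        ankle = heel + foot_pts["ankle"]
        P[:, ankle_id] = ankle
        P[:, knee_id] = _ik_knee(hip, ankle, lt, ls)
    return P


def _measure(traj: Trajectory3D, spec: SyntheticDiveSpec, side: str) -> GroundTruth:
    """Apply the variable definitions to a noiseless trajectory."""
    cm = whole_body_cm(traj)
    events = detect_foot_events(
        traj, side, ground_z=0.0, eps=spec.eps_detect, k=spec.k_detect
    )
    prv, t_prv = find_prv(cm.v_res, events.t_start, events.t_last_contact)
    leg_ref = max(0, int(round(0.2 * spec.pre_dive_duration * spec.fs)))
    variables = compute_dive_variables(
        traj, cm, side, events, prv, t_prv,
        leg_ref_frame=leg_ref, t_first_contact=0,
    )
    return GroundTruth(
        side=side,
        t_start=events.t_start,
        t_last_contact=events.t_last_contact,
        t_final_contact_start=events.t_final_contact_start,
        t_final_off=events.t_final_off,
        t_prv=t_prv,
        variables=variables,
        cm=cm,
        trajectory=traj,
    )


def generate_dive_3d(spec: SyntheticDiveSpec) -> tuple[Trajectory3D, GroundTruth]:
    """Generate a ground-truth dive trajectory and its labels.

    A short deterministic fixed-point calibration rebuilds the motion,
    scaling the speed profile and rotating the heading, until the measured
    peak resultant velocity and frontal departure angle match the requested
    targets; all other targets hold by construction.
    """
    scale, heading = 1.0, spec.departure_angle
    for _ in range(4):
        P = _build_canonical(spec, scale, heading)
        gt = _measure(Trajectory3D(fs=spec.fs, positions=P), spec, "right")
        scale *= spec.peak_speed / gt.variables.prv
        heading = float(np.clip(heading + spec.departure_angle - gt.variables.fda, 0.5, 89.5))

    P = _build_canonical(spec, scale, heading)
    if spec.side == "left":
        P = P[:, MIRROR_MAP, :].copy()
        P[:, :, 1] *= -1.0
    traj = Trajectory3D(fs=spec.fs, positions=P)
    gt = _measure(traj, spec, spec.side)
    return traj, gt


# ---------------------------------------------------------------------------
# camera rigs and rendering
# ---------------------------------------------------------------------------

GOAL_WIDTH = 7.32
GOAL_HEIGHT = 2.44
GOAL_DEPTH = 1.5

_PRESETS = {
    # one camera facing the goal, two diagonal side views
    "field3cam": [
        ("cam_front", (16.0, 0.0, 1.5)),
        ("cam_left", (9.0, 7.0, 2.2)),
        ("cam_right", (9.0, -7.0, 2.2)),
    ],
    "lateral2cam": [
        ("cam_left", (9.0, 7.0, 2.2)),
        ("cam_right", (9.0, -7.0, 2.2)),
    ],
}


def goal_control_points() -> tuple[list[str], np.ndarray]:
    """Eleven surveyed points on the goal frame (front face + back frame)."""
    w = GOAL_WIDTH / 2.0
    pts = [
        ("post_l_base", (0.0, +w, 0.0)),
        ("post_r_base", (0.0, -w, 0.0)),
        ("post_l_top", (0.0, +w, GOAL_HEIGHT)),
        ("post_r_top", (0.0, -w, GOAL_HEIGHT)),
        ("crossbar_mid", (0.0, 0.0, GOAL_HEIGHT)),
        ("goal_line_mid", (0.0, 0.0, 0.0)),
        ("back_l_base", (-GOAL_DEPTH, +w, 0.0)),
        ("back_r_base", (-GOAL_DEPTH, -w, 0.0)),
        ("back_l_mid", (-GOAL_DEPTH, +3.0, 1.2)),
        ("back_r_mid", (-GOAL_DEPTH, -3.0, 1.2)),
        ("back_mid_low", (-GOAL_DEPTH, 0.0, 0.8)),
    ]
    ids = [p[0] for p in pts]
    return ids, np.array([p[1] for p in pts], dtype=float)


def _pinhole_project(
    position: np.ndarray,
    target: np.ndarray,
    pts: np.ndarray,
    f: float = 1600.0,
    cx: float = 960.0,
    cy: float = 540.0,
) -> np.ndarray:
    forward = target - position
    forward = forward / np.linalg.norm(forward)
    right = np.cross(forward, np.array([0.0, 0.0, 1.0]))
    norm_right = np.linalg.norm(right)
    if norm_right < 1e-9:
        raise SpecError("camera optical axis is vertical; offset its position")
    right = right / norm_right
    up = np.cross(right, forward)
    rel = pts - position
    xc = rel @ right
    yc = rel @ up
    zc = rel @ forward
    if np.any(zc <= 0):
        raise SpecError("camera placed inside or behind the working volume")
    return np.stack([cx + f * xc / zc, cy - f * yc / zc], axis=-1)


def make_camera_rig(
    layout: str | list[tuple[str, tuple[float, float, float]]] = "field3cam",
    target: tuple[float, float, float] = (0.0, 0.0, 1.2),
) -> tuple[list[DLTCamera], ControlPointSet]:
    """Build DLT cameras (from ideal pinhole models) plus goal control points.

    ``layout`` is a preset name or a list of ``(camera_id, position)`` pairs;
    at least two cameras are required.
    """
    poses = _PRESETS[layout] if isinstance(layout, str) else list(layout)
    if len(poses) < 2:
        raise SpecError(f"a rig needs >= 2 cameras, got {len(poses)}")
    ids, xyz = goal_control_points()
    tgt = np.asarray(target, dtype=float)
    cameras = []
    uv_per_camera = {}
    for cam_id, position in poses:
        uv = _pinhole_project(np.asarray(position, dtype=float), tgt, xyz)
        cameras.append(calibrate_dlt(xyz, uv, camera_id=cam_id))
        uv_per_camera[cam_id] = uv
    points = ControlPointSet(ids=ids, xyz=xyz, uv_per_camera=uv_per_camera)
    return cameras, points


def render_views(
    traj: Trajectory3D,
    cameras: list[DLTCamera],
    noise_px: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> list[PoseSequence]:
    """Project a trajectory into per-camera keypoint streams.

    Adds i.i.d. Gaussian pixel noise and emits dropouts as confidence-zero
    keypoints; landmarks behind a camera become dropouts as well.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = traj.n_frames
    sequences = []
    for cam in cameras:
        den = traj.positions @ cam.L[8:11] + 1.0
        behind = den <= 1e-9
        safe_den = np.where(behind, 1.0, den)
        u = (traj.positions @ cam.L[0:3] + cam.L[3]) / safe_den
        v = (traj.positions @ cam.L[4:7] + cam.L[7]) / safe_den
        uv = np.stack([u, v], axis=-1)
        if noise_px > 0:
            uv = uv + rng.normal(0.0, noise_px, size=uv.shape)
        conf = rng.uniform(0.5, 0.95, size=(n, 25))
        drop = rng.random((n, 25)) < dropout_rate
        drop |= behind
        conf[drop] = 0.0
        uv[drop] = 0.0
        data = np.concatenate([uv, conf[:, :, None]], axis=-1)
        sequences.append(PoseSequence(camera_id=cam.camera_id, fs=traj.fs, data=data))
    return sequences


# ---------------------------------------------------------------------------
# study-shaped cohorts
# ---------------------------------------------------------------------------

_BASELINES = {
    # (mean, between-subject SD, trial-to-trial SD) in natural units
    "prv": (3.3, 0.25, 0.15),
    "trprv": (0.545, 0.05, 0.035),
    "fsd": (0.37, 0.12, 0.06),
    "dblpp": (0.75, 0.12, 0.05),
    "fda": (14.0, 5.0, 2.5),
}

_BOUNDS = {
    "prv": (1.5, 6.0),
    "trprv": (0.3, 0.9),
    "fsd": (0.05, 1.0),
    "dblpp": (0.3, 1.3),
    "fda": (1.0, 55.0),
}


def _knee_curve(knee_min: float, timing: float, nodes: int, rng) -> np.ndarray:
    x = np.linspace(0.0, 1.0, nodes)
    theta = 168.0 - (168.0 - knee_min) * np.exp(-(((x - timing) / 0.22) ** 2))
    theta += 1.5 * np.sin(2 * np.pi * (x + rng.uniform())) * rng.uniform(0.2, 1.0)
    return theta


def _velocity_curve(prv: float, nodes: int, rng) -> np.ndarray:
    x = np.linspace(0.0, 1.0, nodes)
    v = prv * 0.5 * (1.0 - np.cos(np.pi * x))
    v += 0.04 * prv * np.sin(2 * np.pi * (x + rng.uniform())) * x
    return np.maximum(v, 0.0)


def generate_cohort_variables(
    seed: int = 0,
    n_per_group: int = 4,
    trials_per_cell: int = 4,
    n_nodes: int = 101,
    post_effects: dict[str, float] | None = None,
    laterality_effects: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw a study-shaped table of per-trial dive variables.

    Two groups (CG control, VG video instruction) x ``n_per_group`` subjects
    x pre/post conditions x both dive sides x ``trials_per_cell`` trials.
    ``post_effects`` adds shifts to the VG post condition (e.g.
    ``{"trprv": -0.05}``); ``laterality_effects`` adds shifts to
    non-dominant-side (NDLL) trials.  By default both are zero, giving a
    null cohort.  Returns the trial table plus per-trial normalized speed
    and knee curves keyed by row index.
    """
    rng = np.random.default_rng(seed)
    post_effects = post_effects or {}
    laterality_effects = laterality_effects or {}
    rows = []
    curves_v, curves_k = [], []
    subj_id = 0
    for group in ("CG", "VG"):
        for _ in range(n_per_group):
            subj_id += 1
            base = {
                var: rng.normal(mu, sd_b)
                for var, (mu, sd_b, _) in _BASELINES.items()
            }
            knee_min = rng.normal(115.0, 8.0)
            timing = rng.uniform(0.35, 0.55)
            for condition in ("pre", "post"):
                for side_class in ("DLL", "NDLL"):
                    for trial in range(trials_per_cell):
                        values = {}
                        for var, (_, _, sd_t) in _BASELINES.items():
                            v = base[var] + rng.normal(0.0, sd_t)
                            if group == "VG" and condition == "post":
                                v += post_effects.get(var, 0.0)
                            if side_class == "NDLL":
                                v += laterality_effects.get(var, 0.0)
                            lo, hi = _BOUNDS[var]
                            values[var] = float(np.clip(v, lo, hi))
                        rows.append(
                            {
                                "subject": f"S{subj_id:02d}",
                                "group": group,
                                "condition": condition,
                                "side_class": side_class,
                                "trial": trial,
                                **values,
                            }
                        )
                        curves_v.append(_velocity_curve(values["prv"], n_nodes, rng))
                        curves_k.append(
                            _knee_curve(
                                knee_min + (3.0 if side_class == "NDLL" else 0.0),
                                timing, n_nodes, rng,
                            )
                        )
    table = pd.DataFrame(rows)
    curves = {"v": np.asarray(curves_v), "knee": np.asarray(curves_k)}
    return table, curves


def generate_cohort_specs(
    seed: int = 0,
    n_per_group: int = 2,
    trials_per_cell: int = 1,
    noise_px: float = 0.0,
    dropout_rate: float = 0.0,
    post_effects: dict[str, float] | None = None,
) -> list[tuple[dict, SyntheticDiveSpec]]:
    """Study-shaped list of (labels, dive spec) pairs for full-pipeline runs.

    Spec parameters are drawn per subject around the coached targets; the
    VG post condition receives the ``post_effects`` shifts on the matching
    spec fields (trprv -> impulse_duration, fsd -> step_length,
    fda -> departure_angle, prv -> peak_speed, dblpp -> stance_ratio).
    """
    rng = np.random.default_rng(seed)
    post_effects = post_effects or {}
    field_map = {
        "trprv": "impulse_duration",
        "fsd": "step_length",
        "fda": "departure_angle",
        "prv": "peak_speed",
        "dblpp": "stance_ratio",
    }
    out = []
    subj_id = 0
    for group in ("CG", "VG"):
        for _ in range(n_per_group):
            subj_id += 1
            footed = "right" if rng.random() < 0.75 else "left"
            base = {
                "impulse_duration": float(np.clip(rng.normal(0.55, 0.04), 0.42, 0.7)),
                "step_length": float(np.clip(rng.normal(0.40, 0.06), 0.2, 0.55)),
                "departure_angle": float(np.clip(rng.normal(15.0, 4.0), 4.0, 35.0)),
                "peak_speed": float(np.clip(rng.normal(3.3, 0.2), 2.5, 4.2)),
                "stance_ratio": float(np.clip(rng.normal(0.76, 0.06), 0.6, 0.95)),
                "leg_length": float(np.clip(rng.normal(0.88, 0.04), 0.75, 1.0)),
                "height": float(np.clip(rng.normal(1.82, 0.08), 1.6, 2.0)),
                "body_mass": float(np.clip(rng.normal(80.0, 10.0), 55.0, 110.0)),
            }
            for condition in ("pre", "post"):
                for dive_side in ("left", "right"):
                    side_class = "DLL" if dive_side == footed else "NDLL"
                    for trial in range(trials_per_cell):
                        params = dict(base)
                        if group == "VG" and condition == "post":
                            for var, shift in post_effects.items():
                                key = field_map[var]
                                params[key] = params[key] + shift
                        spec = SyntheticDiveSpec(
                            side=dive_side,
                            noise_px=noise_px,
                            dropout_rate=dropout_rate,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            **params,
                        )
                        labels = {
                            "subject": f"S{subj_id:02d}",
                            "group": group,
                            "condition": condition,
                            "side": dive_side,
                            "side_class": side_class,
                            "trial": trial,
                        }
                        out.append((labels, spec))
    return out
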