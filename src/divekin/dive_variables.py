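"""The six per-trial dive outcome variables.

PRV    peak resultant CM velocity (m/s) within the impulse window.
TRPRV  time from first ipsilateral foot-off to the PRV frame (s).
FSD    frontal step distance (m): anteroposterior big-toe displacement
       between the first foot-off and the final departure, signed toward
       the penalty mark (+X).
DBLPP  heel-to-heel distance in the preparatory posture divided by leg
       length (stored as a unitless ratio; x100 gives the percentage form).
FDA    frontal departure angle (deg): horizontal-plane angle of the CM
       displacement, between the first and last ipsilateral ground contact,
       measured from the mediolateral axis (0 deg = parallel to the goal
       line, 90 deg = straight toward the penalty mark).
Knee   interior knee flexion/extension angle of the ipsilateral leg,
       time-normalized over the impulse cycle (101 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_model import CMTrajectory, SIDE_LANDMARKS, Trajectory3D, knee_angle
from .dive_events import FootEvents, normalize_cycle
from .errors import MissingLandmarkError, UndefinedAngleError

__all__ = [
    "DiveVariables",
    "compute_trprv",
    "compute_fsd",
    "leg_length",
    "compute_dblpp",
    "compute_fda",
    "compute_dive_variables",
]


@dataclass
class DiveVariables:
    """The six scalar/curve outcomes of one dive trial."""

    prv: float
    trprv: float
    fsd: float
    dblpp: float
    fda: float
    knee_curve: np.ndarray = field(repr=False)
    v_curve: np.ndarray | None = field(default=None, repr=False)

    @property
    def dblpp_percent(self) -> float:
        return 100.0 * self.dblpp


def compute_trprv(t_start: int, t_prv: int, fs: float) -> float:
    """Time (s) from the first ipsilateral foot-off to the PRV frame."""
    if t_prv <= t_start:
        raise ValueError(f"t_prv ({t_prv}) must exceed t_start ({t_start})")
    return (t_prv - t_start) / fs


def _landmark(traj: Trajectory3D, landmark_id: int, frame: int) -> np.ndarray:
    p = traj.positions[frame, landmark_id]
    if np.isnan(p).any():
        raise MissingLandmarkError(f"landmark {landmark_id} missing at frame {frame}")
    return p


def compute_fsd(
    traj: Trajectory3D, side: str, t_start: int, t_final_off: int
) -> float:
    """Frontal step distance: big-toe X displacement between first foot-off
    and the first frame of the final off-period, positive toward +X."""
    toe = SIDE_LANDMARKS[side]["big_toe"]
    x0 = _landmark(traj, toe, t_start)[0]
    x1 = _landmark(traj, toe, t_final_off)[0]
    return float(x1 - x0)


def leg_length(traj: Trajectory3D, side: str, t_ref: int) -> float:
    """Leg length (m): |hip-knee| + |knee-ankle'| at a reference frame.

    ``ankle'`` is the ankle with its vertical coordinate replaced by the
    heel's, extrapolating the shank to the point nearest the ground.
    """
    ids = SIDE_LANDMARKS[side]
    hip = _landmark(traj, ids["hip"], t_ref)
    knee = _landmark(traj, ids["knee"], t_ref)
    ankle = _landmark(traj, ids["ankle"], t_ref).copy()
    heel = _landmark(traj, ids["heel"], t_ref)
    ankle[2] = heel[2]
    return float(np.linalg.norm(hip - knee) + np.linalg.norm(knee - ankle))


def compute_dblpp(traj: Trajectory3D, t_ref: int, leg_len: float) -> float:
    """Heel-to-heel distance at the preparatory-posture frame over leg length.

    ``t_ref`` is the first frame of the final ipsilateral contact period
    (the posture from which the dive departs).  Returned as a unitless
    ratio; multiply by 100 for the percentage form.
    """
    if leg_len <= 0:
        raise ValueError(f"leg length must be positive, got {leg_len}")
    heel_l = _landmark(traj, SIDE_LANDMARKS["left"]["heel"], t_ref)
    heel_r = _landmark(traj, SIDE_LANDMARKS["right"]["heel"], t_ref)
    return float(np.linalg.norm(heel_l - heel_r) / leg_len)


def compute_fda(
    cm: CMTrajectory, t_first_contact: int, t_last_contact: int
) -> float:
    """Frontal departure angle (deg) of the horizontal CM displacement.

    The angle between the CM displacement (first to last ipsilateral ground
    contact, horizontal plane) and the mediolateral axis:
    ``atan(|dX| / |dY|)``.
    """
    delta = cm.cm[t_last_contact] - cm.cm[t_first_contact]
    dx, dy = abs(delta[0]), abs(delta[1])
    if np.hypot(dx, dy) < 1e-9:
        raise UndefinedAngleError(
            "CM displacement in the horizontal plane is ~0; FDA undefined"
        )
    return float(np.degrees(np.arctan2(dx, dy)))


def compute_dive_variables(
    traj: Trajectory3D,
    cm: CMTrajectory,
    side: str,
    events: FootEvents,
    prv: float,
    t_prv: int,
    leg_ref_frame: int = 0,
    t_first_contact: int = 0,
    n_nodes: int = 101,
) -> DiveVariables:
    """Assemble the six outcome variables from trajectory, CM and events."""
    fs = traj.fs
    knee = knee_angle(traj, side)
    return DiveVariables(
        prv=prv,
        trprv=compute_trprv(events.t_start, t_prv, fs),
        fsd=compute_fsd(traj, side, events.t_start, events.t_final_off),
        dblpp=compute_dblpp(
            traj,
            events.t_final_contact_start,
            leg_length(traj, side, leg_ref_frame),
        ),
        fda=compute_fda(cm, t_first_contact, events.t_last_contact),
        knee_curve=normalize_cycle(knee, events.t_start, t_prv, n_nodes),
        v_curve=normalize_cycle(cm.v_res, events.t_start, t_prv, n_nodes),
    )
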