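"""Dive-cycle event detection and 0-100% time normalization.

The diving impulse cycle begins when the foot ipsilateral to the dive side
leaves the ground for the first time and ends at the frame of peak resultant
CM velocity (PRV).  The PRV is searched from the cycle start up to the last
ipsilateral ground contact plus a 6-frame lookahead (50 ms at 120 Hz), so
that free-fall acceleration after departure cannot masquerade as impulse.
Ground contact is decided from landmark heights: the foot counts as "off"
when both the heel and the big toe exceed ``ground_z + eps`` for at least
``k`` consecutive frames.  Curves are compared across trials after linear
resampling onto a 101-node 0-100% grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .body_model import CMTrajectory, SIDE_LANDMARKS, Trajectory3D
from .errors import (
    AmbiguousSideError,
    BadTrialError,
    EventWindowError,
    NoDiveError,
)

__all__ = [
    "DiveCycle",
    "FootEvents",
    "detect_dive_side",
    "estimate_ground_z",
    "detect_foot_events",
    "find_prv",
    "normalize_cycle",
]

N_NODES = 101


@dataclass
class FootEvents:
    """Ipsilateral foot contact chronology.

    t_start : first frame of the first sustained off-period (cycle start).
    t_last_contact : last ground-contact frame before the final off-period.
    t_final_contact_start : first frame of the final contact period (the
        preparatory posture after the frontal step lands).
    t_final_off : first frame of the final sustained off-period.
    off_periods : list of (start, stop) frame pairs, stop exclusive.
    """

    t_start: int
    t_last_contact: int
    t_final_contact_start: int
    t_final_off: int
    off_periods: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class DiveCycle:
    """Dive side, key frames, and the normalized-grid node count."""

    side: str
    t_start: int
    t_last_contact: int
    t_prv: int
    n_nodes: int = N_NODES

    def __post_init__(self) -> None:
        if not self.t_start <= self.t_last_contact < self.t_prv:
            raise EventWindowError(
                f"cycle ordering violated: t_start={self.t_start}, "
                f"t_last_contact={self.t_last_contact}, t_prv={self.t_prv}"
            )


def detect_dive_side(
    cm: CMTrajectory,
    min_displacement: float = 0.2,
    y_positive_side: str = "left",
) -> str:
    """Dive side from the sign of the net mediolateral CM displacement.

    With the field frame oriented X toward the penalty mark and Z up, the
    goalkeeper's left maps to +Y (configurable via ``y_positive_side``).
    """
    if cm.cm.shape[0] < 10:
        raise AmbiguousSideError("need >= 10 frames to decide the dive side")
    dy = float(cm.cm[-1, 1] - cm.cm[0, 1])
    if abs(dy) < min_displacement:
        raise AmbiguousSideError(
            f"net mediolateral displacement {dy:.3f} m below "
            f"{min_displacement} m; cannot decide dive side"
        )
    other = "right" if y_positive_side == "left" else "left"
    return y_positive_side if dy > 0 else other


def estimate_ground_z(
    traj: Trajectory3D,
    standing_frames: int = 48,
    percentile: float = 5.0,
) -> float:
    """Ground height: a low percentile of foot-landmark Z in the standing phase."""
    foot_ids = [
        SIDE_LANDMARKS[s][k] for s in ("left", "right") for k in ("heel", "big_toe")
    ]
    window = traj.positions[: max(standing_frames, 1), foot_ids, 2]
    return float(np.percentile(window, percentile))


def _off_mask(
    traj: Trajectory3D, side: str, ground_z: float, eps: float, k: int
) -> np.ndarray:
    """Frames where the ipsilateral foot is off the ground, sustained >= k."""
    ids = SIDE_LANDMARKS[side]
    heel_z = traj.positions[:, ids["heel"], 2]
    toe_z = traj.positions[:, ids["big_toe"], 2]
    raw = (heel_z > ground_z + eps) & (toe_z > ground_z + eps)
    # Keep only runs of >= k consecutive off frames.
    mask = np.zeros_like(raw)
    for start, stop in _runs(raw):
        if stop - start >= k:
            mask[start:stop] = True
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) of maximal True runs, stop exclusive."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_foot_events(
    traj: Trajectory3D,
    side: str,
    ground_z: float = 0.0,
    eps: float = 0.03,
    k: int = 3,
) -> FootEvents:
    """Locate ipsilateral foot-off and ground-contact events.

    A frontal-step dive produces two off-periods (the step flight and the
    final departure): the cycle starts at the first off-period and the last
    contact is the final grounded frame before the final off-period.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    off = _off_mask(traj, side, ground_z, eps, k)
    periods = _runs(off)
    if not periods:
        raise NoDiveError(f"{side} foot never leaves the ground")
    if off.all():
        raise BadTrialError(f"{side} foot never detected on the ground")

    t_start = int(periods[0][0])
    t_final_off = int(periods[-1][0])
    if t_final_off == 0:
        raise BadTrialError(f"{side} foot off the ground from the first frame")
    contact_before = np.flatnonzero(~off[:t_final_off])
    t_last_contact = int(contact_before[-1])
    # Start of the contact run that t_last_contact belongs to.
    run_start = t_last_contact
    while run_start > 0 and not off[run_start - 1]:
        run_start -= 1
    return FootEvents(
        t_start=t_start,
        t_last_contact=t_last_contact,
        t_final_contact_start=int(run_start),
        t_final_off=t_final_off,
        off_periods=[(int(a), int(b)) for a, b in periods],
    )


def find_prv(
    v_res: np.ndarray,
    t_start: int,
    t_last_contact: int,
    lookahead: int = 6,
) -> tuple[float, int]:
    """Peak resultant velocity and its frame within the impulse window.

    The window runs from ``t_start`` to ``t_last_contact + lookahead``
    (6 frames = 50 ms at 120 Hz), clamped to the series end with a warning;
    ties break to the first maximum.
    """
    v_res = np.asarray(v_res, dtype=float)
    end = t_last_contact + lookahead
    if end > v_res.size - 1:
        warnings.warn(
            f"PRV window end {end} clamped to series end {v_res.size - 1}",
            stacklevel=2,
        )
        end = v_res.size - 1
    if end < t_start or t_start < 0:
        raise EventWindowError(
            f"empty PRV window [{t_start}, {end}] for series of length {v_res.size}"
        )
    window = v_res[t_start : end + 1]
    i = int(np.argmax(window))
    return float(window[i]), t_start + i


def normalize_cycle(
    series: np.ndarray,
    t_start: int,
    t_prv: int,
    n_nodes: int = N_NODES,
) -> np.ndarray:
    """Resample a series onto ``n_nodes`` equally spaced points over the cycle.

    Node 0 carries the value at ``t_start`` and the last node the value at
    ``t_prv`` (linear interpolation in between).
    """
    series = np.asarray(series, dtype=float)
    if t_prv <= t_start:
        raise EventWindowError(f"t_prv ({t_prv}) must exceed t_start ({t_start})")
    if t_prv - t_start < 1 or t_prv > series.size - 1:
        raise EventWindowError("cycle window not covered by the series")
    nodes = np.linspace(t_start, t_prv, n_nodes)
    return np.interp(nodes, np.arange(series.size), series)
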