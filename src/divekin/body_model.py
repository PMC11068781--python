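"""Segmental whole-body centre of mass, CM velocity and knee angle.

The 25 BODY_25 landmarks are mapped onto 14 body segments (head, trunk and
left/right upper arms, forearms, hands, thighs, shanks, feet).  Each segment
carries a standardized mass fraction and a centre-of-mass position ratio
measured from its proximal landmark; the whole-body CM is the mass-weighted
sum of the segment CMs (the segmental method).  The default table ships with
de Leva-style male parameters adapted to the landmark set: the head segment
runs neck-to-nose as a midpoint proxy (no vertex landmark exists), hands
collapse onto the wrists (no finger landmarks), and feet run heel-to-big-toe.
The table is a plain CSV and fully user-replaceable; it is validated on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingLandmarkError, UndefinedAngleError

__all__ = [
    "LANDMARKS",
    "SIDE_LANDMARKS",
    "Trajectory3D",
    "AnthropometricTable",
    "CMTrajectory",
    "load_anthropometric_table",
    "whole_body_cm",
    "cm_velocity",
    "knee_angle",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

# BODY_25 landmark ids used throughout the package.
LANDMARKS = {
    "nose": 0, "neck": 1,
    "r_shoulder": 2, "r_elbow": 3, "r_wrist": 4,
    "l_shoulder": 5, "l_elbow": 6, "l_wrist": 7,
    "mid_hip": 8,
    "r_hip": 9, "r_knee": 10, "r_ankle": 11,
    "l_hip": 12, "l_knee": 13, "l_ankle": 14,
    "r_eye": 15, "l_eye": 16, "r_ear": 17, "l_ear": 18,
    "l_big_toe": 19, "l_small_toe": 20, "l_heel": 21,
    "r_big_toe": 22, "r_small_toe": 23, "r_heel": 24,
}

SIDE_LANDMARKS = {
    "right": {"hip": 9, "knee": 10, "ankle": 11, "big_toe": 22, "heel": 24},
    "left": {"hip": 12, "knee": 13, "ankle": 14, "big_toe": 19, "heel": 21},
}


@dataclass
class Trajectory3D:
    """Per-frame 3D positions (m) of the 25 landmarks in the field frame.

    ``positions`` has shape (n_frames, 25, 3) ordered (X anteroposterior,
    Y mediolateral, Z vertical).
    """

    fs: float
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (25, 3):
            raise ValueError(
                f"positions must have shape (n_frames, 25, 3), got {self.positions.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class AnthropometricTable:
    """Segment definitions: endpoints, mass fractions and CM position ratios."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"segment", "proximal_id", "distal_id", "mass_fraction", "cm_ratio"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"anthropometric table missing columns {sorted(missing)}")
        total = self.table["mass_fraction"].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total!r}, expected 1")
        if ((self.table["cm_ratio"] < 0) | (self.table["cm_ratio"] > 1)).any():
            raise ValueError("cm_ratio values must lie in [0, 1]")
        for col in ("proximal_id", "distal_id"):
            ids = self.table[col]
            if ((ids < 0) | (ids > 24)).any():
                raise ValueError(f"{col} values must be BODY_25 ids 0..24")

    @property
    def proximal(self) -> np.ndarray:
        return self.table["proximal_id"].to_numpy(dtype=int)

    @property
    def distal(self) -> np.ndarray:
        return self.table["distal_id"].to_numpy(dtype=int)

    @property
    def mass_fraction(self) -> np.ndarray:
        return self.table["mass_fraction"].to_numpy(dtype=float)

    @property
    def cm_ratio(self) -> np.ndarray:
        return self.table["cm_ratio"].to_numpy(dtype=float)


@dataclass
class CMTrajectory:
    """Whole-body CM positions (m) and resultant speed (m/s) per frame."""

    fs: float
    cm: np.ndarray = field(repr=False)
    v_res: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=float)
        self.v_res = np.asarray(self.v_res, dtype=float)
        if self.cm.shape[0] != self.v_res.shape[0]:
            raise ValueError("cm and v_res must have equal length")


def load_anthropometric_table(path: str | Path | None = None) -> AnthropometricTable:
    """Load the default packaged table, or a user CSV, validating it."""
    if path is None:
        with resources.files("divekin.data").joinpath("anthropometry.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return AnthropometricTable(table=df)


def whole_body_cm(
    traj: Trajectory3D,
    table: AnthropometricTable | None = None,
    body_mass: float | None = None,
) -> CMTrajectory:
    """Whole-body CM by the segmental method, plus resultant CM speed.

    Per frame, each segment CM is ``proximal + ratio * (distal - proximal)``
    and the whole-body CM is the mass-fraction-weighted sum.  ``body_mass``
    (kg) only scales reported segment masses, never the CM position.
    """
    if table is None:
        table = load_anthropometric_table()
    P = traj.positions
    used = np.union1d(table.proximal, table.distal)
    bad = np.isnan(P[:, used]).any(axis=2)
    if bad.any():
        t, j = np.argwhere(bad)[0]
        raise MissingLandmarkError(
            f"landmark {used[j]} missing (NaN) at frame {t}"
        )
    prox = P[:, table.proximal, :]
    dist = P[:, table.distal, :]
    seg_cm = prox + table.cm_ratio[None, :, None] * (dist - prox)
    cm = np.einsum("s,tsc->tc", table.mass_fraction, seg_cm)
    v_res = cm_velocity(cm, traj.fs)
    return CMTrajectory(fs=traj.fs, cm=cm, v_res=v_res)


def cm_velocity(cm: np.ndarray, fs: float) -> np.ndarray:
    """Resultant CM speed (m/s): central differences, one-sided at the ends."""
    cm = np.asarray(cm, dtype=float)
    if cm.shape[0] < 3:
        raise ValueError(f"need >= 3 frames for velocity, got {cm.shape[0]}")
    vel = np.gradient(cm, 1.0 / fs, axis=0)
    return np.linalg.norm(vel, axis=1)


def knee_angle(traj: Trajectory3D, side: str) -> np.ndarray:
    """Interior 3D knee angle (deg) of the chosen side, per frame.

    The angle at the knee between the knee->hip and knee->ankle vectors;
    180 deg is full extension.  (The flexion convention, 180 minus this,
    is a one-liner for callers who prefer it.)
    """
    ids = SIDE_LANDMARKS[side]
    P = traj.positions
    hip = P[:, ids["hip"]]
    knee = P[:, ids["knee"]]
    ankle = P[:, ids["ankle"]]
    u = hip - knee
    w = ankle - knee
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    degenerate = (nu < 1e-12) | (nw < 1e-12)
    if degenerate.any():
        raise UndefinedAngleError(
            f"zero-length thigh or shank vector at frame {int(np.nonzero(degenerate)[0][0])}"
        )
    cross = np.linalg.norm(np.cross(u, w), axis=1)
    dot = np.einsum("tc,tc->t", u, w)
    return np.degrees(np.arctan2(cross, dot))


def write_trajectory_csv(traj: Trajectory3D, path: str | Path) -> None:
    """Write a trajectory as long-format CSV (frame, landmark_id, X, Y, Z)."""
    n = traj.n_frames
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), 25),
            "landmark_id": np.tile(np.arange(25), n),
            "X": traj.positions[:, :, 0].ravel(),
            "Y": traj.positions[:, :, 1].ravel(),
            "Z": traj.positions[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path, fs: float = 120.0) -> Trajectory3D:
    df = pd.read_csv(path)
    n = df["frame"].max() + 1
    positions = np.full((n, 25, 3), np.nan)
    positions[df["frame"].to_numpy(int), df["landmark_id"].to_numpy(int)] = df[
        ["X", "Y", "Z"]
    ].to_numpy(float)
    return Trajectory3D(fs=fs, positions=positions)
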