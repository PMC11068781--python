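"""11-parameter DLT camera calibration and multi-camera 3D reconstruction.

The direct linear transformation (DLT) maps a world point ``(X, Y, Z)`` in
metres to image coordinates ``(u, v)`` in pixels through 11 coefficients::

    u = (L1 X + L2 Y + L3 Z + L4) / (L9 X + L10 Y + L11 Z + 1)
    v = (L5 X + L6 Y + L7 Z + L8) / (L9 X + L10 Y + L11 Z + 1)

Calibration solves the linearized system from >= 6 non-coplanar surveyed
control points; reconstruction triangulates a 3D point from two or more
calibrated views by stacked linear least squares.  The world frame is the
field frame: X anteroposterior (toward the penalty mark), Y mediolateral,
Z vertical, origin at the centre of the goal line on the ground.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InsufficientPointsError,
    InsufficientViewsError,
)

__all__ = [
    "DLTCamera",
    "ControlPointSet",
    "calibrate_dlt",
    "project",
    "reconstruct_3d",
    "reconstruct_series",
    "self_reconstruction_error",
    "read_control_points",
    "write_cameras",
    "read_cameras",
]

MIN_CONTROL_POINTS = 6
COPLANARITY_TOL = 1e-3


@dataclass
class DLTCamera:
    """A calibrated camera: label plus the 11 DLT coefficients."""

    camera_id: str
    L: np.ndarray = field(repr=False)
    reprojection_rmse: float | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float).ravel()
        if self.L.size != 11:
            raise ValueError(f"expected 11 DLT coefficients, got {self.L.size}")


@dataclass
class ControlPointSet:
    """Surveyed 3D control points and their per-camera image observations."""

    ids: list[str]
    xyz: np.ndarray  # (N, 3) metres
    uv_per_camera: dict[str, np.ndarray]  # camera_id -> (N, 2) pixels

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.uv_per_camera = {
            k: np.asarray(v, dtype=float) for k, v in self.uv_per_camera.items()
        }


def _check_volume(xyz: np.ndarray) -> None:
    centred = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    ratio = s[-1] / s[0] if s[0] > 0 else 0.0
    if ratio < COPLANARITY_TOL:
        raise DegenerateGeometryError(
            f"control points are near-coplanar: singular-value ratio "
            f"{ratio:.2e} < {COPLANARITY_TOL:.0e}"
        )


def calibrate_dlt(
    xyz: np.ndarray, uv: np.ndarray, camera_id: str = "cam"
) -> DLTCamera:
    """Fit the 11 DLT coefficients from control points by least squares.

    Parameters
    ----------
    xyz : (N, 3) world coordinates in metres, N >= 6, non-coplanar.
    uv : (N, 2) observed image coordinates in pixels.

    Returns the camera with its control-point reprojection RMSE attached.
    """
    xyz = np.asarray(xyz, dtype=float)
    uv = np.asarray(uv, dtype=float)
    n = xyz.shape[0]
    if n < MIN_CONTROL_POINTS:
        raise InsufficientPointsError(
            f"{camera_id}: DLT needs >= {MIN_CONTROL_POINTS} control points, got {n}"
        )
    _check_volume(xyz)

    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    X, Y, Z = xyz.T
    u, v = uv.T
    A[0::2, 0:3] = xyz
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -u[:, None] * xyz
    A[1::2, 4:7] = xyz
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -v[:, None] * xyz
    b[0::2] = u
    b[1::2] = v
    L, *_ = np.linalg.lstsq(A, b, rcond=None)

    cam = DLTCamera(camera_id=camera_id, L=L)
    residual = project(cam, xyz) - uv
    cam.reprojection_rmse = float(np.sqrt(np.mean(residual**2)))
    return cam


def project(camera: DLTCamera, xyz: np.ndarray) -> np.ndarray:
    """Forward DLT projection of one point (3,) or many (..., 3) to pixels."""
    xyz = np.asarray(xyz, dtype=float)
    single = xyz.ndim == 1
    pts = np.atleast_2d(xyz)
    L = camera.L
    den = pts @ L[8:11] + 1.0
    if np.any(den <= 0):
        raise BehindCameraError(
            f"{camera.camera_id}: non-positive DLT denominator "
            f"(point behind camera plane)"
        )
    u = (pts @ L[0:3] + L[3]) / den
    v = (pts @ L[4:7] + L[7]) / den
    uv = np.stack([u, v], axis=-1)
    return uv[0] if single else uv.reshape(*xyz.shape[:-1], 2)


def _stack_rows(camera: DLTCamera, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two linearized triangulation rows for one camera observation."""
    L = camera.L
    u, v = uv
    A = np.array([L[0:3] - u * L[8:11], L[4:7] - v * L[8:11]])
    b = np.array([u - L[3], v - L[7]])
    return A, b


def reconstruct_3d(
    cameras: list[DLTCamera],
    observations: list[np.ndarray | None],
    return_residual: bool = False,
):
    """Triangulate one 3D point from >= 2 camera observations.

    ``observations[i]`` is the (u, v) seen by ``cameras[i]`` or None when the
    view is missing; all valid views are used.  Returns the least-squares
    world point in metres (and optionally the image-plane residual RMS).
    """
    rows_A, rows_b = [], []
    for cam, obs in zip(cameras, observations):
        if obs is None:
            continue
        A, b = _stack_rows(cam, np.asarray(obs, dtype=float))
        rows_A.append(A)
        rows_b.append(b)
    if len(rows_A) < 2:
        raise InsufficientViewsError(
            f"3D reconstruction needs >= 2 observations, got {len(rows_A)}"
        )
    A = np.vstack(rows_A)
    b = np.concatenate(rows_b)
    xyz, *_ = np.linalg.lstsq(A, b, rcond=None)
    if return_residual:
        res = float(np.sqrt(np.mean((A @ xyz - b) ** 2)))
        return xyz, res
    return xyz


def reconstruct_series(
    cameras: list[DLTCamera],
    uv: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized triangulation of many points.

    Parameters
    ----------
    uv : ndarray, shape (n_cameras, ..., 2)
        Image observations per camera; trailing axes are arbitrary (e.g.
        frames x landmarks).
    weights : ndarray, shape (n_cameras, ...), optional
        0/1 validity per observation.  Points with fewer than two valid
        views come back as NaN.

    Returns world points with shape ``(..., 3)``.
    """
    uv = np.asarray(uv, dtype=float)
    C = uv.shape[0]
    lead = uv.shape[1:-1]
    flat_uv = uv.reshape(C, -1, 2)
    n_pts = flat_uv.shape[1]
    w = (
        np.ones((C, n_pts))
        if weights is None
        else np.asarray(weights, dtype=float).reshape(C, n_pts)
    )

    # Normal equations accumulated over cameras: x = (A^T A)^-1 A^T b.
    M = np.zeros((n_pts, 3, 3))
    y = np.zeros((n_pts, 3))
    for c, cam in enumerate(cameras):
        L = cam.L
        u = flat_uv[c, :, 0]
        v = flat_uv[c, :, 1]
        a1 = L[0:3][None, :] - u[:, None] * L[8:11][None, :]
        a2 = L[4:7][None, :] - v[:, None] * L[8:11][None, :]
        b1 = u - L[3]
        b2 = v - L[7]
        wc = w[c][:, None, None]
        M += wc * (a1[:, :, None] * a1[:, None, :] + a2[:, :, None] * a2[:, None, :])
        y += w[c][:, None] * (a1 * b1[:, None] + a2 * b2[:, None])

    ok = w.sum(axis=0) >= 2
    out = np.full((n_pts, 3), np.nan)
    if ok.any():
        out[ok] = np.linalg.solve(M[ok], y[ok][..., None])[..., 0]
    return out.reshape(*lead, 3)


def self_reconstruction_error(
    cameras: list[DLTCamera], points: ControlPointSet
) -> np.ndarray:
    """Per-axis mean absolute error of reconstructing the calibration object.

    Every control point is triangulated back from its own image observations
    and compared with its surveyed position; the result is the mean absolute
    error separately along X (anteroposterior), Y (mediolateral) and
    Z (vertical), in metres.
    """
    errors = []
    for i in range(points.xyz.shape[0]):
        obs = [points.uv_per_camera[cam.camera_id][i] for cam in cameras]
        rec = reconstruct_3d(cameras, obs)
        errors.append(rec - points.xyz[i])
    return np.mean(np.abs(np.asarray(errors)), axis=0)


def read_control_points(path: str | Path) -> ControlPointSet:
    """Load control points from CSV (id, X, Y, Z, camera_id, u, v)."""
    df = pd.read_csv(path)
    ids = sorted(df["id"].unique().tolist())
    xyz = np.array(
        [df.loc[df["id"] == i, ["X", "Y", "Z"]].iloc[0].to_numpy() for i in ids]
    )
    uv_per_camera: dict[str, np.ndarray] = {}
    for cam_id, sub in df.groupby("camera_id"):
        sub = sub.set_index("id")
        uv_per_camera[str(cam_id)] = np.array(
            [sub.loc[i, ["u", "v"]].to_numpy(dtype=float) for i in ids]
        )
    return ControlPointSet(ids=[str(i) for i in ids], xyz=xyz, uv_per_camera=uv_per_camera)


def write_cameras(cameras: list[DLTCamera], path: str | Path) -> None:
    payload = [
        {"camera_id": c.camera_id, "L": c.L.tolist(), "reprojection_rmse": c.reprojection_rmse}
        for c in cameras
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_cameras(path: str | Path) -> list[DLTCamera]:
    payload = json.loads(Path(path).read_text())
    return [
        DLTCamera(
            camera_id=item["camera_id"],
            L=np.asarray(item["L"]),
            reprojection_rmse=item.get("reprojection_rmse"),
        )
        for item in payload
    ]
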