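"""Pinhole-camera 3D localization of a segmented fruit.

Given the completed fruit silhouette, a restored depth map and the
camera intrinsics, the fruit's transverse diameters come from
back-projecting the silhouette's extreme points at their depths
(dx = X_C - X_A, dy = Y_D - Y_B), the depth-axis diameter dz from a
quadratic polynomial in (dx, dy) calibrated on caliper-measured fruit,
and the fruit centre from the 2D box centre back-projected at its
restored depth.  The result is packaged as an axis-aligned 3D bounding
box with front face at the fruit surface depth Zq and back face at
Zq + dz, plus the image projections of its eight vertices.

Conventions: camera frame in mm, Z along the optical axis; pixels are
0-based with u = column, v = row, origin at the image's top-left.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .losses import BBox2D
from .segmentation import SegmentationResult

logger = logging.getLogger(__name__)

__all__ = [
    "CameraIntrinsics",
    "DzModel",
    "DzFitReport",
    "Localization3D",
    "project",
    "backproject",
    "diameters_xy",
    "estimate_dz",
    "fit_dz_model",
    "center_distance",
    "box3d_vertices",
    "localize_fruit",
    "DEFAULT_DZ_MODEL",
]


class BehindCameraError(ValueError):
    """Point has non-positive depth and cannot be projected."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels.

    Optionally constructed from the physical focal length f (mm) and pixel
    pitches du, dv (mm/px) via fx = f/du, fy = f/dv.
    """

    fx: float
    fy: float
    u0: float
    v0: float

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")

    @classmethod
    def from_physical(cls, f: float, du: float, dv: float, u0: float, v0: float):
        return cls(fx=f / du, fy=f / dv, u0=u0, v0=v0)

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.u0], [0.0, self.fy, self.v0], [0.0, 0.0, 1.0]]
        )


# Calibration of the depth-axis diameter polynomial on 137 caliper-measured
# fruits (coefficients in mm; dx, dy in mm).
@dataclass(frozen=True)
class DzModel:
    b0: float = 16.0728
    b1: float = 0.0028
    b2: float = 0.0018
    b3: float = 0.0264
    b4: float = 0.4133

    def coefficients(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3, self.b4])


DEFAULT_DZ_MODEL = DzModel()


@dataclass(frozen=True)
class DzFitReport:
    rmse: float  # mm
    r_squared: float


@dataclass(frozen=True)
class Localization3D:
    """Complete 3D description of one fruit in the camera frame (mm)."""

    dx: float
    dy: float
    dz: float
    Q0: tuple[float, float, float]
    d: float
    vertices: tuple[tuple[float, float, float], ...]  # P1..P8
    projections: tuple[tuple[float, float], ...]  # p1..p8

    def to_dict(self) -> dict:
        return {
            "dx_mm": self.dx,
            "dy_mm": self.dy,
            "dz_mm": self.dz,
            "Q0": list(self.Q0),
            "d_mm": self.d,
            "vertices": [list(p) for p in self.vertices],
            "projections": [list(p) for p in self.projections],
        }


def project(P, K: CameraIntrinsics) -> tuple[float, float]:
    """Perspective projection (X, Y, Z) mm -> (u, v) px; requires Z > 0."""
    X, Y, Z = (float(c) for c in P)
    if Z <= 0:
        raise BehindCameraError(f"cannot project point with Z={Z} <= 0")
    return (K.fx * X / Z + K.u0, K.fy * Y / Z + K.v0)


def backproject(u: float, v: float, Z: float, K: CameraIntrinsics) -> tuple[float, float, float]:
    """Inverse pinhole map: pixel plus depth -> camera-frame point (mm)."""
    if Z <= 0:
        raise BehindCameraError(f"cannot backproject at depth Z={Z} <= 0")
    return ((u - K.u0) * Z / K.fx, (v - K.v0) * Z / K.fy, float(Z))


def diameters_xy(A3, B3, C3, D3) -> tuple[float, float]:
    """Transverse diameters from the back-projected extreme points.

    dx spans leftmost A to rightmost C along X; dy spans topmost B to
    bottom-most D along Y.  Non-positive spans indicate a degenerate or
    mis-oriented region.
    """
    dx = float(C3[0]) - float(A3[0])
    dy = float(D3[1]) - float(B3[1])
    if dx <= 0 or dy <= 0:
        raise ValueError(f"degenerate diameters dx={dx:.3f}, dy={dy:.3f}")
    return dx, dy


def estimate_dz(dx: float, dy: float, model: DzModel = DEFAULT_DZ_MODEL) -> float:
    """Depth-axis diameter from the quadratic polynomial in (dx, dy)."""
    if dx <= 0 or dy <= 0:
        raise ValueError("dx and dy must be positive")
    dz = model.b0 + model.b1 * dx**2 + model.b2 * dy**2 + model.b3 * dx + model.b4 * dy
    if dz <= 0:
        raise ValueError(f"model produced non-positive dz={dz:.3f} mm")
    return float(dz)


def fit_dz_model(samples) -> tuple[DzModel, DzFitReport]:
    """Ordinary least squares of dz on [1, dx^2, dy^2, dx, dy].

    ``samples`` is an iterable of (dx, dy, dz) in mm; at least 5 samples
    and a full-rank design are required.
    """
    a = np.asarray(list(samples), dtype=np.float64).reshape(-1, 3)
    if a.shape[0] < 5:
        raise ValueError(f"need at least 5 samples, got {a.shape[0]}")
    dx, dy, dz = a.T
    design = np.column_stack([np.ones_like(dx), dx**2, dy**2, dx, dy])
    if np.linalg.matrix_rank(design) < 5:
        raise ValueError("rank-deficient design: dx/dy values do not span the model")
    beta, _, _, _ = np.linalg.lstsq(design, dz, rcond=None)
    resid = dz - design @ beta
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((dz - dz.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return DzModel(*map(float, beta)), DzFitReport(rmse=rmse, r_squared=r2)


def center_distance(Q0) -> float:
    """Euclidean distance from the fruit centre to the camera origin (mm)."""
    return float(math.hypot(*(float(c) for c in Q0)))


def box3d_vertices(Q0, dx: float, dy: float, dz: float) -> tuple[tuple[float, float, float], ...]:
    """Eight vertices of the axis-aligned fruit box.

    P1-P4 form the back face (Z = Zq + dz) counter-clockwise starting at
    P1 = (Xq - dx/2, Yq + dy/2, Zq + dz); P5-P8 repeat the same angular
    order on the front face (Z = Zq).
    """
    if min(dx, dy, dz) <= 0:
        raise ValueError("box diameters must be positive")
    Xq, Yq, Zq = (float(c) for c in Q0)
    hx, hy = dx / 2.0, dy / 2.0
    corners = [(-hx, +hy), (+hx, +hy), (+hx, -hy), (-hx, -hy)]
    back = [(Xq + cx, Yq + cy, Zq + dz) for cx, cy in corners]
    front = [(Xq + cx, Yq + cy, Zq) for cx, cy in corners]
    return tuple(back + front)


def _depth_at(depth: np.ndarray, u: int, v: int, region: np.ndarray, step: str) -> float:
    """Restored depth at (u, v); if missing there, nearest region pixel's."""
    z = float(depth[v, u])
    if z > 0:
        return z
    vs, us = np.nonzero(region & (depth > 0))
    if vs.size == 0:
        raise ValueError(f"{step}: no restored depth available in the fruit region")
    i = int(np.argmin((us - u) ** 2 + (vs - v) ** 2))
    logger.info("%s: depth missing at (%d, %d); using nearest region pixel (%d, %d)",
                step, u, v, int(us[i]), int(vs[i]))
    return float(depth[vs[i], us[i]])


def localize_fruit(
    seg: SegmentationResult,
    depth: np.ndarray,
    box: BBox2D,
    K: CameraIntrinsics,
    model: DzModel = DEFAULT_DZ_MODEL,
    center_from: str = "box",
) -> Localization3D:
    """Full localization of one fruit from segmentation plus restored depth.

    ``depth`` must be in the same crop frame as the segmentation masks and
    complete over the convex region.  Steps: extreme points -> back-project
    A,B,C,D at their restored depths -> dx, dy -> dz polynomial -> centre
    Q0 from the 2D box centre (or the region centroid with
    ``center_from='centroid'``) back-projected at its restored depth ->
    distance d -> 3D box vertices -> their image projections.
    """
    depth = np.asarray(depth, dtype=np.float64)
    if depth.shape != seg.convex_mask.shape:
        raise ValueError("depth map and segmentation masks have different shapes")
    ou, ov = seg.crop_origin
    region = seg.convex_mask

    def abs_backproject(pt_crop, step):
        uc, vc = pt_crop
        z = _depth_at(depth, int(round(uc)), int(round(vc)), region, step)
        return backproject(uc + ou, vc + ov, z, K)

    e = seg.extremes
    A3 = abs_backproject(e.A, "S2:A")
    B3 = abs_backproject(e.B, "S2:B")
    C3 = abs_backproject(e.C, "S2:C")
    D3 = abs_backproject(e.D, "S2:D")
    dx, dy = diameters_xy(A3, B3, C3, D3)
    dz = estimate_dz(dx, dy, model)

    if center_from == "box":
        cu_abs, cv_abs = box.center
    elif center_from == "centroid":
        vs, us = np.nonzero(region)
        cu_abs, cv_abs = float(us.mean()) + ou, float(vs.mean()) + ov
    else:
        raise ValueError("center_from must be 'box' or 'centroid'")
    cu_crop = min(max(int(round(cu_abs - ou)), 0), depth.shape[1] - 1)
    cv_crop = min(max(int(round(cv_abs - ov)), 0), depth.shape[0] - 1)
    if not region[cv_crop, cu_crop]:
        vs, us = np.nonzero(region)
        i = int(np.argmin((us - cu_crop) ** 2 + (vs - cv_crop) ** 2))
        logger.info("S4: centre pixel outside the fruit region; using nearest region pixel")
        cu_crop, cv_crop = int(us[i]), int(vs[i])
    Zq = _depth_at(depth, cu_crop, cv_crop, region, "S4:center")
    Q0 = backproject(cu_abs, cv_abs, Zq, K)
    d = center_distance(Q0)
    vertices = box3d_vertices(Q0, dx, dy, dz)
    projections = tuple(project(P, K) for P in vertices)
    return Localization3D(dx=dx, dy=dy, dz=dz, Q0=Q0, d=d,
                          vertices=vertices, projections=projections)
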