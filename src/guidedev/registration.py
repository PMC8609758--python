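"""Closed-form least-squares rigid superimposition from paired named fiducials.

Pre- and post-operative frames are aligned the way image-guided surgery
does it: anatomical landmarks are marked with the same names in both
frames and the proper rigid transform minimising

    sum_i || R m_i + t - f_i ||^2

is obtained in closed form — centroid subtraction, singular-value
decomposition of the cross-covariance, with the sign of the smallest
singular direction corrected so that det(R) = +1 (a reflection is never
returned).  Correspondence is by landmark *label*, order-independent, all
landmarks equally weighted.  The fiducial registration error (FRE) is the
RMS of the per-landmark residual distances after alignment.

An optional similarity fit (``allow_scale=True``) additionally estimates a
single isotropic scale; the default is a pure 6-dof rigid fit, since both
frames image the same physical models.

Landmark files use the 3D Slicer markups fiducial (FCSV) dialect; see
:func:`read_fcsv` / :func:`write_fcsv`.  Coordinates are taken verbatim
(no LPS/RAS re-signing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_geometry import BurPose
from .exceptions import (
    CorrespondenceError,
    DegenerateLandmarksError,
    InsufficientLandmarksError,
)

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "RegistrationReport",
    "fit_rigid",
    "apply_transform",
    "invert",
    "compose",
    "read_fcsv",
    "write_fcsv",
    "save_transform_text",
    "load_transform_text",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class LandmarkSet:
    """Named fiducial points of one frame (mm)."""

    labels: tuple[str, ...]
    points: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(labels) != len(pts):
            raise ValueError(f"{len(labels)} labels for {len(pts)} points")
        if len(set(labels)) != len(labels):
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.labels)

    def reordered(self, labels: Sequence[str]) -> "LandmarkSet":
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            idx = [index[l] for l in labels]
        except KeyError as err:
            raise CorrespondenceError(f"label {err.args[0]!r} not present in frame {self.frame_id!r}")
        return LandmarkSet(tuple(labels), self.points[idx], self.frame_id)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid (optionally similarity) map ``x -> scale * R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1, no reflection)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def apply_pose(self, pose: BurPose) -> BurPose:
        return BurPose(self.apply_points(pose.base), self.apply_points(pose.tip))

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return RigidTransform(Rinv, -s * Rinv @ self.translation, s)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.scale * self.rotation @ first.translation + self.translation,
            self.scale * first.scale,
        )

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix (scale folded into the linear block)."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        A = m[:3, :3]
        scale = float(np.cbrt(np.linalg.det(A)))
        return cls(A / scale, m[:3, 3], scale)

    def to_json_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]), float(d.get("scale", 1.0)))


@dataclass(frozen=True)
class RegistrationReport:
    """Fit result: the transform, per-landmark residuals and their RMS (FRE)."""

    transform: RigidTransform
    residuals_mm: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "residuals_mm", np.asarray(self.residuals_mm, dtype=float))

    @property
    def fre_mm(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_mm**2)))


def fit_rigid(moving: LandmarkSet, fixed: LandmarkSet, allow_scale: bool = False) -> RegistrationReport:
    """Least-squares fit of the transform mapping ``moving`` onto ``fixed``.

    Correspondence is by label name (order-independent).  Raises
    :class:`CorrespondenceError` on mismatched label sets,
    :class:`InsufficientLandmarksError` below three correspondences, and
    :class:`DegenerateLandmarksError` for (near-)collinear configurations.
    """
    if set(moving.labels) != set(fixed.labels):
        only_m = set(moving.labels) - set(fixed.labels)
        only_f = set(fixed.labels) - set(moving.labels)
        raise CorrespondenceError(
            f"label sets differ (only in moving: {sorted(only_m)}, only in fixed: {sorted(only_f)})"
        )
    if len(moving) < 3:
        raise InsufficientLandmarksError(f"need at least 3 landmarks, got {len(moving)}")

    order = sorted(moving.labels)
    M = moving.reordered(order).points
    F = fixed.reordered(order).points

    mc = M.mean(axis=0)
    fc = F.mean(axis=0)
    M0 = M - mc
    F0 = F - fc

    H = M0.T @ F0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 <=> collinear (or coincident) landmarks: rotation about the
    # line is unobservable
    if S[1] <= _ORTHO_TOL * max(S[0], _ORTHO_TOL):
        raise DegenerateLandmarksError("landmarks are collinear; rotation is not identifiable")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    if allow_scale:
        var_m = float(np.sum(M0**2))
        scale = float(np.sum(S * np.diag(D)) / var_m)
    else:
        scale = 1.0

    t = fc - scale * R @ mc
    transform = RigidTransform(R, t, scale)
    residuals = np.linalg.norm(transform.apply_points(M) - F, axis=1)
    return RegistrationReport(transform=transform, residuals_mm=residuals, labels=tuple(order))


def apply_transform(T: RigidTransform, p: BurPose) -> BurPose:
    """Map a pose through ``T`` (base and tip each sent to ``s R x + t``)."""
    return T.apply_pose(p)


def invert(T: RigidTransform) -> RigidTransform:
    return T.inverse()


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """Composite applying ``T1`` first, then ``T2``."""
    return T2.compose(T1)


# ---------------------------------------------------------------------------
# FCSV (3D Slicer markups fiducial) dialect

_FCSV_COLUMNS = "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"


def read_fcsv(path: str | Path, frame_id: str | None = None) -> LandmarkSet:
    """Read landmarks from an FCSV file.

    Lines starting ``#`` are headers; a ``# columns = ...`` header, when
    present, locates the x/y/z/label fields, otherwise the standard markups
    column order is assumed.  Coordinates are taken verbatim.
    """
    path = Path(path)
    columns = _FCSV_COLUMNS.split(",")
    labels: list[str] = []
    points: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header = line.lstrip("#").strip()
            if header.lower().startswith("columns"):
                columns = [c.strip() for c in header.split("=", 1)[1].split(",")]
            continue
        parts = line.split(",")
        ix, iy, iz = (columns.index(c) for c in ("x", "y", "z"))
        il = columns.index("label") if "label" in columns else len(parts) - 1
        il = il if il < len(parts) else len(parts) - 1
        points.append([float(parts[ix]), float(parts[iy]), float(parts[iz])])
        labels.append(parts[il])
    return LandmarkSet(tuple(labels), np.array(points).reshape(-1, 3), frame_id or path.stem)


def write_fcsv(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks as a minimal valid Slicer markups fiducial file."""
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        f"# columns = {_FCSV_COLUMNS}",
    ]
    for i, (label, p) in enumerate(zip(landmarks.labels, landmarks.points)):
        x, y, z = (repr(float(v)) for v in p)
        lines.append(f"vtkMRMLMarkupsFiducialNode_{i},{x},{y},{z},0,0,0,1,1,1,0,{label},,")
    Path(path).write_text("\n".join(lines) + "\n")


def save_transform_text(T: RigidTransform, path: str | Path) -> None:
    """Write the 4×4 homogeneous matrix as 16 row-major floats (4 per line)."""
    np.savetxt(path, T.as_matrix(), fmt="%.17g")


def load_transform_text(path: str | Path) -> RigidTransform:
    return RigidTransform.from_matrix(np.loadtxt(path))


def save_transform_json(T: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(T.to_json_dict(), indent=2) + "\n")


def load_transform_json(path: str | Path) -> RigidTransform:
    return RigidTransform.from_json_dict(json.loads(Path(path).read_text()))
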