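"""Drill-path poses and planned-versus-executed deviation metrics.

A drill path is a directed cylinder axis segment running from its coronal
end (the *base*, where the bur enters the tooth) to its apical end (the
*tip*).  All coordinates are millimetres in a single right-handed world
frame; any voxel/world conversion happens at I/O, never here.

The accuracy of a guided access cavity relative to its virtual plan is
summarised by three statistics measured after superimposing the planning
and post-operative frames:

* **coronal deviation** — Euclidean distance between the two bases (mm),
* **apical deviation**  — Euclidean distance between the two tips (mm),
* **angular deviation** — angle between the two *directed* base→tip axes
  (degrees, in ``[0, 180)``).

Axes are directed deliberately: planned and executed paths share the
coronal→apical orientation, so an anti-parallel pair (180°) signals a
reversed-axis input rather than a perfect hit.  Angles are reported in
degrees at full floating precision; rounding (two decimals, half-up) is a
report-time concern only.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import InvalidPoseError

__all__ = [
    "BurPose",
    "DeviationTriple",
    "SleeveSpec",
    "CanalTarget",
    "angular_deviation",
    "coronal_deviation",
    "apical_deviation",
    "measure_deviations",
    "round_half_up",
    "read_bur_poses",
    "write_bur_poses",
    "iter_pose_pairs",
    "POSE_CSV_COLUMNS",
]

#: Required columns of the bur-pose CSV interchange format.
POSE_CSV_COLUMNS = [
    "case_id",
    "group",
    "role",
    "base_x",
    "base_y",
    "base_z",
    "tip_x",
    "tip_y",
    "tip_z",
]


def _as_point(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise InvalidPoseError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidPoseError(f"{name} contains non-finite coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class BurPose:
    """A directed drill-path segment from coronal ``base`` to apical ``tip`` (mm)."""

    base: np.ndarray
    tip: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", _as_point(self.base, "base"))
        object.__setattr__(self, "tip", _as_point(self.tip, "tip"))
        if self.length <= 0.0:
            raise InvalidPoseError("pose has zero length (base == tip)")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.tip - self.base))

    @property
    def axis(self) -> np.ndarray:
        """Unit direction base→tip."""
        return (self.tip - self.base) / self.length


@dataclass(frozen=True)
class DeviationTriple:
    """The three accuracy statistics of one drill path (mm, mm, degrees)."""

    coronal_mm: float
    apical_mm: float
    angular_deg: float

    def __post_init__(self) -> None:
        for name in ("coronal_mm", "apical_mm", "angular_deg"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0.0:
                raise InvalidPoseError(f"{name} must be finite and non-negative, got {v}")
            object.__setattr__(self, name, v)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.coronal_mm, self.apical_mm, self.angular_deg)


@dataclass(frozen=True)
class SleeveSpec:
    """Guide-sleeve geometry: bore inner diameter, bur shank diameter, sleeve height (mm).

    The diametral clearance ``inner - bur`` is the mechanical play that
    bounds the intrinsic angular error of the guide.
    """

    inner_diameter_mm: float
    bur_diameter_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        for name in ("inner_diameter_mm", "bur_diameter_mm", "height_mm"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be positive, got {v}")
            object.__setattr__(self, name, v)
        if self.inner_diameter_mm < self.bur_diameter_mm:
            raise ValueError(
                "sleeve inner diameter must be at least the bur shank diameter "
                f"({self.inner_diameter_mm} < {self.bur_diameter_mm})"
            )

    @property
    def clearance_mm(self) -> float:
        """Diametral play between bur shank and sleeve bore (mm)."""
        return self.inner_diameter_mm - self.bur_diameter_mm


@dataclass(frozen=True)
class CanalTarget:
    """Geometric stand-in for a root-canal orifice used by the synthetic
    accessibility rule: the real study records accessibility empirically
    with a size-10 K-file, which we cannot reproduce in silico."""

    entry: np.ndarray
    axis: np.ndarray
    orifice_radius_mm: float = field(default=1.5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry", _as_point(self.entry, "entry"))
        ax = _as_point(self.axis, "axis")
        norm = np.linalg.norm(ax)
        if norm <= 0:
            raise InvalidPoseError("canal axis must be a non-zero vector")
        object.__setattr__(self, "axis", ax / norm)
        if not self.orifice_radius_mm > 0:
            raise ValueError("orifice_radius_mm must be positive")


def _check_pose(p: BurPose, name: str) -> None:
    if not isinstance(p, BurPose):
        raise InvalidPoseError(f"{name} must be a BurPose, got {type(p).__name__}")


def angular_deviation(a: BurPose, b: BurPose) -> float:
    """Angle between the directed axes of two poses, degrees in ``[0, 180)``.

    Symmetric in its arguments.  The angle is taken between the directed
    axes (no folding), so anti-parallel axes score near 180°.  Computed as
    ``2 atan2(|u - v|, |u + v|)`` — equal to ``arccos(u . v)`` but
    numerically exact near 0 and 180 degrees.
    """
    _check_pose(a, "a")
    _check_pose(b, "b")
    u, v = a.axis, b.axis
    return float(
        np.degrees(2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v)))
    )


def coronal_deviation(a: BurPose, b: BurPose) -> float:
    """Euclidean distance between the two bases, mm."""
    _check_pose(a, "a")
    _check_pose(b, "b")
    return float(np.linalg.norm(a.base - b.base))


def apical_deviation(a: BurPose, b: BurPose) -> float:
    """Euclidean distance between the two tips, mm."""
    _check_pose(a, "a")
    _check_pose(b, "b")
    return float(np.linalg.norm(a.tip - b.tip))


def measure_deviations(virtual: BurPose, actual: BurPose) -> DeviationTriple:
    """Bundle the three deviation statistics of an executed path against its plan.

    Both poses must already be expressed in the same frame (register first
    if they are not).
    """
    return DeviationTriple(
        coronal_mm=coronal_deviation(virtual, actual),
        apical_mm=apical_deviation(virtual, actual),
        angular_deg=angular_deviation(virtual, actual),
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of the reported tables),
    unlike banker's rounding of the builtin :func:`round`."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Bur-pose CSV interchange


def read_bur_poses(path: str | Path) -> pd.DataFrame:
    """Read a bur-pose table (one row per pose; roles ``virtual``/``actual``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bur-pose CSV {path} is missing columns: {missing}")
    return df


def write_bur_poses(df: pd.DataFrame, path: str | Path) -> None:
    """Write a bur-pose table; required columns first, extras preserved after."""
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bur-pose table is missing columns: {missing}")
    extras = [c for c in df.columns if c not in POSE_CSV_COLUMNS]
    df[POSE_CSV_COLUMNS + extras].to_csv(path, index=False)


def _pose_from_row(row: pd.Series) -> BurPose:
    return BurPose(
        base=[row["base_x"], row["base_y"], row["base_z"]],
        tip=[row["tip_x"], row["tip_y"], row["tip_z"]],
    )


def iter_pose_pairs(df: pd.DataFrame) -> Iterator[tuple[str, str, BurPose, BurPose, pd.Series]]:
    """Yield ``(case_id, group, virtual_pose, actual_pose, virtual_row)`` per case.

    Raises ``ValueError`` on a case that does not have exactly one virtual
    and one actual row.
    """
    for case_id, sub in df.groupby("case_id", sort=False):
        roles = sub.set_index("role")
        if sorted(roles.index) != ["actual", "virtual"]:
            raise ValueError(
                f"case {case_id!r} must have exactly one 'virtual' and one 'actual' row, "
                f"got roles {list(sub['role'])}"
            )
        vrow = roles.loc["virtual"]
        arow = roles.loc["actual"]
        yield str(case_id), str(vrow["group"]), _pose_from_row(vrow), _pose_from_row(arow), vrow
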