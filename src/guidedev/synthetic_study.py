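"""Synthetic replica of the ex-vivo guided-access accuracy experiment.

The generator emulates the full study so every downstream stage —
registration, deviation measurement, group statistics, ROC — is testable
without imaging data:

* **Drill paths.**  For each case a 16-mm planned pose is placed in the
  planning (pre-operative) frame; the executed pose is the plan perturbed
  by (i) an isotropic 2-D base offset perpendicular to the planned axis
  (per-axis sd calibrated so the Rayleigh magnitude mean equals the
  reported per-group coronal mean), (ii) a tilt about the executed base
  with uniform azimuth and half-normal magnitude (scale calibrated so the
  half-normal mean equals the reported per-group angular mean), and (iii)
  independent Gaussian tip-localisation jitter (default one CBCT voxel,
  0.15 mm per axis).  The apical deviation is *emergent* from this
  geometry — a tilt t displaces a 16-mm tip by about 32·sin(t/2) mm — and
  its group means exceed the reported apical means, which are mutually
  incompatible with rigid 16-mm paths (see docs/methods.md).

* **Accessibility.**  The real study probes each cavity with a size-10
  K-file; in silico we use a transparent geometric stand-in: a canal
  target sits at the planned tip with the planned axis, and a case is
  accessible iff the executed tip lands within ``orifice_radius_mm`` of
  the target entry *and* the executed axis is within
  ``max_entry_angle_deg`` of the canal axis.  The default knobs are
  calibrated so the default study reproduces the reported inaccessible
  fraction (23/117) and the reported discrimination ordering
  (angular > apical > coronal).

* **Frames.**  Cases are distributed over six jaw models.  Each model has
  a pre-operative landmark frame; the post-operative frame is a random
  rigid transform of it plus iid Gaussian localisation noise.  Executed
  poses are exported in the post-operative frame, so the pipeline must
  register before measuring — exactly the superimposition step of the
  real workflow.

Everything is reproducible under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import reference
from .core_geometry import (
    BurPose,
    CanalTarget,
    DeviationTriple,
    angular_deviation,
    measure_deviations,
    read_bur_poses,
    write_bur_poses,
)
from .exceptions import ConfigError
from .registration import LandmarkSet, RigidTransform, read_fcsv, write_fcsv

__all__ = [
    "StudyConfig",
    "CaseRecord",
    "ModelFrames",
    "SyntheticStudy",
    "generate_study",
    "write_study",
    "read_study",
]


def _default_group_sizes() -> dict[str, int]:
    return dict(reference.GROUP_SIZES)


def _default_coronal_sd() -> dict[str, float]:
    return {g: float(reference.calibrated_coronal_sd(g)) for g in reference.GROUPS}


def _default_tilt_scale() -> dict[str, float]:
    return {g: float(reference.calibrated_tilt_scale(g)) for g in reference.GROUPS}


@dataclass
class StudyConfig:
    """Parameters of one synthetic study.

    Error scales default to the calibration of the reference experiment;
    the accessibility-rule knobs (``orifice_radius_mm``,
    ``max_entry_angle_deg``) and the tip jitter are this package's own
    calibration, not reported facts.
    """

    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    coronal_sd_mm: Mapping[str, float] = field(default_factory=_default_coronal_sd)
    tilt_scale_deg: Mapping[str, float] = field(default_factory=_default_tilt_scale)
    apical_jitter_sd_mm: float = 0.15
    bur_length_mm: float = reference.BUR_WORKING_LENGTH_MM
    n_models: int = 6
    landmarks_per_model: int = 6
    landmark_noise_sd_mm: float = 0.1
    transform_rotation_max_deg: float = 10.0
    transform_translation_max_mm: float = 5.0
    orifice_radius_mm: float = 1.5
    max_entry_angle_deg: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = dict(self.group_sizes)
        self.coronal_sd_mm = dict(self.coronal_sd_mm)
        self.tilt_scale_deg = dict(self.tilt_scale_deg)
        self.validate()

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigError("group_sizes must name at least one group")
        for g, n in self.group_sizes.items():
            if int(n) < 1:
                raise ConfigError(f"group size for {g!r} must be >= 1, got {n}")
            if g not in self.coronal_sd_mm or g not in self.tilt_scale_deg:
                raise ConfigError(f"missing error scales for group {g!r}")
        for name in ("apical_jitter_sd_mm", "landmark_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for scales in (self.coronal_sd_mm, self.tilt_scale_deg):
            for g, v in scales.items():
                if v < 0:
                    raise ConfigError(f"error scale for {g!r} must be >= 0, got {v}")
        if self.bur_length_mm <= 0:
            raise ConfigError("bur_length_mm must be positive")
        if self.n_models < 1 or self.landmarks_per_model < 3:
            raise ConfigError("need >= 1 model and >= 3 landmarks per model")
        if not self.orifice_radius_mm > 0:
            raise ConfigError("orifice_radius_mm must be positive")
        if self.max_entry_angle_deg < 0:
            raise ConfigError("max_entry_angle_deg must be >= 0")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    @property
    def n_cases(self) -> int:
        return int(sum(self.group_sizes.values()))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class CaseRecord:
    """One drill path: plan, executed path (planning frame), canal stand-in,
    accessibility flag and the true deviation triple."""

    case_id: str
    group: str
    model_id: int
    planned: BurPose
    actual: BurPose
    canal: CanalTarget
    accessible: bool
    true_deviations: DeviationTriple


@dataclass(frozen=True)
class ModelFrames:
    """Pre/post landmark frames of one jaw model and the true inter-frame map
    (pre -> post)."""

    model_id: int
    pre: LandmarkSet
    post: LandmarkSet
    true_transform: RigidTransform


@dataclass
class SyntheticStudy:
    config: StudyConfig
    cases: list[CaseRecord]
    frames: dict[int, ModelFrames]

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth per-case table (deviations measured in the planning frame)."""
        rows = [
            {
                "case_id": c.case_id,
                "group": c.group,
                "model_id": c.model_id,
                "coronal_mm": c.true_deviations.coronal_mm,
                "apical_mm": c.true_deviations.apical_mm,
                "angular_deg": c.true_deviations.angular_deg,
                "accessible": c.accessible,
            }
            for c in self.cases
        ]
        return pd.DataFrame(rows)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, helper))
    return e1, np.cross(axis, e1)


def _random_planned_pose(rng: np.random.Generator, length: float) -> BurPose:
    # base somewhere in a jaw-sized volume, axis within a 30 degree cone of
    # "apically down"
    base = rng.uniform([0.0, 0.0, 0.0], [60.0, 40.0, 20.0])
    tilt = np.radians(rng.uniform(0.0, 30.0))
    az = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.array(
        [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), -np.cos(tilt)]
    )
    return BurPose(base, base + length * axis)


def _tilted_axis(axis: np.ndarray, tilt_rad: float, azimuth_rad: float) -> np.ndarray:
    """Rotate a unit axis by ``tilt_rad`` towards the perpendicular direction
    given by ``azimuth_rad`` (exact geodesic step on the unit sphere)."""
    e1, e2 = _perpendicular_basis(axis)
    direction = np.cos(azimuth_rad) * e1 + np.sin(azimuth_rad) * e2
    return np.cos(tilt_rad) * axis + np.sin(tilt_rad) * direction


def _random_rigid(rng: np.random.Generator, max_angle_deg: float, max_translation_mm: float) -> RigidTransform:
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    axis = _unit(rng.normal(size=3))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from ``config`` (reproducible)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.bur_length_mm

    frames: dict[int, ModelFrames] = {}
    for m in range(config.n_models):
        pre_pts = rng.uniform([0.0, 0.0, 0.0], [60.0, 40.0, 20.0], size=(config.landmarks_per_model, 3))
        labels = tuple(f"L{j}" for j in range(config.landmarks_per_model))
        T = _random_rigid(rng, config.transform_rotation_max_deg, config.transform_translation_max_mm)
        post_pts = T.apply_points(pre_pts)
        if config.landmark_noise_sd_mm > 0:
            post_pts = post_pts + rng.normal(0.0, config.landmark_noise_sd_mm, size=post_pts.shape)
        frames[m] = ModelFrames(
            model_id=m,
            pre=LandmarkSet(labels, pre_pts, frame_id=f"model{m}_pre"),
            post=LandmarkSet(labels, post_pts, frame_id=f"model{m}_post"),
            true_transform=T,
        )

    cases: list[CaseRecord] = []
    idx = 0
    for group, n in config.group_sizes.items():
        sd_c = float(config.coronal_sd_mm[group])
        scale_t = np.radians(float(config.tilt_scale_deg[group]))
        for _ in range(int(n)):
            planned = _random_planned_pose(rng, L)
            e1, e2 = _perpendicular_basis(planned.axis)
            offset = rng.normal(0.0, sd_c, size=2) if sd_c > 0 else np.zeros(2)
            base = planned.base + offset[0] * e1 + offset[1] * e2
            tilt = abs(rng.normal(0.0, scale_t)) if scale_t > 0 else 0.0
            azimuth = rng.uniform(0.0, 2.0 * np.pi)
            if tilt > 0:
                tip = base + L * _tilted_axis(planned.axis, tilt, azimuth)
            else:
                # keep the untilted tip exact (no axis renormalisation residue)
                tip = planned.tip + (base - planned.base)
            if config.apical_jitter_sd_mm > 0:
                tip = tip + rng.normal(0.0, config.apical_jitter_sd_mm, size=3)
            actual = BurPose(base, tip)

            canal = CanalTarget(
                entry=planned.tip,
                axis=planned.axis,
                orifice_radius_mm=config.orifice_radius_mm,
            )
            tip_dist = float(np.linalg.norm(actual.tip - canal.entry))
            entry_angle = angular_deviation(actual, planned)
            accessible = bool(
                tip_dist <= canal.orifice_radius_mm and entry_angle <= config.max_entry_angle_deg
            )
            cases.append(
                CaseRecord(
                    case_id=f"{group}{idx:03d}",
                    group=group,
                    model_id=idx % config.n_models,
                    planned=planned,
                    actual=actual,
                    canal=canal,
                    accessible=accessible,
                    true_deviations=measure_deviations(planned, actual),
                )
            )
            idx += 1
    return SyntheticStudy(config=config, cases=cases, frames=frames)


# ---------------------------------------------------------------------------
# study I/O


def _pose_row(case: CaseRecord, role: str, pose: BurPose) -> dict:
    return {
        "case_id": case.case_id,
        "group": case.group,
        "role": role,
        "base_x": pose.base[0],
        "base_y": pose.base[1],
        "base_z": pose.base[2],
        "tip_x": pose.tip[0],
        "tip_y": pose.tip[1],
        "tip_z": pose.tip[2],
        "model_id": case.model_id,
    }


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write a study to ``directory`` in the module interchange formats.

    ``poses.csv`` holds virtual poses in the planning frame and actual
    poses in the post-operative frame (as a real post-op scan would);
    ``cases.csv`` holds group/model/accessibility bookkeeping;
    ``model{k}_{pre,post}.fcsv`` the landmark frames; ``truth.json`` the
    generator ground truth (config echo, true transforms, true deviations).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    rows = []
    for c in study.cases:
        T = study.frames[c.model_id].true_transform
        rows.append(_pose_row(c, "virtual", c.planned))
        rows.append(_pose_row(c, "actual", T.apply_pose(c.actual)))
    poses = pd.DataFrame(rows)
    out["poses"] = directory / "poses.csv"
    write_bur_poses(poses, out["poses"])

    cases = pd.DataFrame(
        [
            {"case_id": c.case_id, "group": c.group, "model_id": c.model_id, "accessible": c.accessible}
            for c in study.cases
        ]
    )
    out["cases"] = directory / "cases.csv"
    cases.to_csv(out["cases"], index=False)

    for m, fr in study.frames.items():
        for which, ls in (("pre", fr.pre), ("post", fr.post)):
            p = directory / f"model{m}_{which}.fcsv"
            write_fcsv(ls, p)
            out[f"model{m}_{which}"] = p

    truth = {
        "config": study.config.to_dict(),
        "seed": study.config.seed,
        "accessibility_rule": "synthetic geometric stand-in (not an empirical K-file test)",
        "true_transforms": {
            str(m): fr.true_transform.to_json_dict() for m, fr in study.frames.items()
        },
        "true_deviations": {
            c.case_id: list(c.true_deviations.as_tuple()) for c in study.cases
        },
    }
    out["truth"] = directory / "truth.json"
    out["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out


def read_study(directory: str | Path) -> dict:
    """Read back a written study directory.

    Returns a dict with ``poses`` (DataFrame), ``cases`` (DataFrame),
    ``frames`` (model_id -> (pre, post) LandmarkSets) and ``truth``
    (parsed ground-truth JSON, absent for user-supplied data).
    """
    directory = Path(directory)
    bundle: dict = {
        "poses": read_bur_poses(directory / "poses.csv"),
        "frames": {},
        "cases": None,
        "truth": None,
    }
    cases_path = directory / "cases.csv"
    if cases_path.exists():
        bundle["cases"] = pd.read_csv(cases_path)
    truth_path = directory / "truth.json"
    if truth_path.exists():
        bundle["truth"] = json.loads(truth_path.read_text())
    for pre_path in sorted(directory.glob("model*_pre.fcsv")):
        m = int(pre_path.stem.replace("model", "").replace("_pre", ""))
        post_path = directory / f"model{m}_post.fcsv"
        if post_path.exists():
            bundle["frames"][m] = (read_fcsv(pre_path), read_fcsv(post_path))
    return bundle
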