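"""End-to-end orchestration: simulate → register → measure → analyze → report.

A run either generates a synthetic study from a :class:`StudyConfig` or
consumes a user-supplied data directory (bur-pose CSV plus optional
``model{k}_{pre,post}.fcsv`` landmark pairs and a ``cases.csv`` with
accessibility labels).  Executed poses are mapped into the planning
(pre-operative) frame through the fitted per-model transform before any
deviation is measured — the superimposition direction of the imaging
workflow (post onto pre).  Every run writes a manifest (config snapshot,
seed, input checksums, stage timings, output list) that makes stochastic
outputs bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_geometry import SleeveSpec, iter_pose_pairs, measure_deviations, round_half_up
from .intrinsic_error import sleeve_tolerance
from .reference import STUDY_SLEEVE
from .registration import fit_rigid
from .stats_roc import METRICS, AnalysisResult, analyze_study, write_analysis
from .synthetic_study import StudyConfig, generate_study, read_study, write_study

__all__ = ["RunManifest", "run_pipeline", "process_study_dir", "report"]


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    version: str
    inputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _measure(bundle: dict, log: list[str]) -> pd.DataFrame:
    """Register per-model frames and measure deviations in the planning frame."""
    poses = bundle["poses"]
    transforms = {}
    for m, (pre, post) in bundle["frames"].items():
        # moving = post-operative frame, fixed = planning frame
        rep = fit_rigid(moving=post, fixed=pre)
        transforms[m] = rep.transform
        log.append(f"model {m}: registered {len(pre)} landmarks, FRE = {rep.fre_mm:.4f} mm")
    if not transforms:
        log.append("no landmark frames found; poses assumed to share one frame")

    has_model = "model_id" in poses.columns
    rows = []
    for case_id, group, virtual, actual, vrow in iter_pose_pairs(poses):
        if transforms:
            if not has_model:
                raise ValueError("landmark frames supplied but poses.csv lacks a model_id column")
            m = int(vrow["model_id"])
            if m not in transforms:
                raise ValueError(f"case {case_id!r} references model {m} with no landmark frames")
            actual = transforms[m].apply_pose(actual)
        d = measure_deviations(virtual, actual)
        rows.append(
            {
                "case_id": case_id,
                "group": group,
                "coronal_mm": d.coronal_mm,
                "apical_mm": d.apical_mm,
                "angular_deg": d.angular_deg,
            }
        )
    table = pd.DataFrame(rows)
    cases = bundle.get("cases")
    if cases is not None and "accessible" in cases.columns:
        table = table.merge(cases[["case_id", "accessible"]], on="case_id", how="left")
        if table["accessible"].isna().any():
            missing = table.loc[table["accessible"].isna(), "case_id"].tolist()
            raise ValueError(f"cases.csv lacks accessibility labels for {missing}")
    return table


def process_study_dir(data_dir: str | Path, out_dir: str | Path) -> tuple[pd.DataFrame, AnalysisResult]:
    """Register, measure and analyze an existing study directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    bundle = read_study(Path(data_dir))
    table = _measure(bundle, log)
    result = analyze_study(table)
    return table, result


def run_pipeline(
    out_dir: str | Path,
    config: StudyConfig | None = None,
    data_dir: str | Path | None = None,
    seed: int | None = None,
    sleeve: SleeveSpec = STUDY_SLEEVE,
    verbose: bool = False,
) -> RunManifest:
    """Run the full pipeline into ``out_dir``.

    Exactly one of ``config`` (synthetic mode; ``seed`` overrides the
    config seed) or ``data_dir`` (user-supplied files) must be given.
    """
    if (config is None) == (data_dir is None):
        raise ValueError("supply exactly one of config (synthetic) or data_dir (user files)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"guidedev {__version__}"]
    manifest = RunManifest(config={}, seed=seed, version=__version__)

    t0 = time.perf_counter()
    if config is not None:
        if seed is not None:
            config = StudyConfig.from_dict({**config.to_dict(), "seed": int(seed)})
        manifest.seed = config.seed
        manifest.config = config.to_dict()
        log.append(f"simulate: {config.n_cases} cases, seed {config.seed}")
        study = generate_study(config)
        data_dir = out_dir / "raw"
        write_study(study, data_dir)
        manifest.timings_s["simulate"] = time.perf_counter() - t0

    data_dir = Path(data_dir)
    t1 = time.perf_counter()
    bundle = read_study(data_dir)
    for p in sorted(data_dir.iterdir()):
        if p.is_file():
            manifest.inputs[str(p)] = _sha256(p)
    table = _measure(bundle, log)
    table.to_csv(out_dir / "deviations.csv", index=False)
    manifest.timings_s["register_measure"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    result = analyze_study(table)
    for w in result.warnings:
        log.append(f"warning: {w}")
    files = write_analysis(result, out_dir)
    manifest.timings_s["analyze"] = time.perf_counter() - t2

    text = report(result, sleeve=sleeve)
    (out_dir / "report.txt").write_text(text)
    if verbose:
        print(text)
    manifest.outputs = sorted(
        str(p) for p in [out_dir / "deviations.csv", out_dir / "report.txt", *files.values()]
    )
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    manifest.write(out_dir / "manifest.json")
    return manifest


def _fmt(x: float, nd: int) -> str:
    return f"{round_half_up(x, nd):.{nd}f}"


def report(
    result: AnalysisResult,
    sleeve: SleeveSpec | None = STUDY_SLEEVE,
    drilling_depth_mm: float | None = None,
) -> str:
    """Human-readable summary: deviation table (2-decimal, half-up), AUC
    table (3-decimal) and the sleeve intrinsic-error block."""
    groups = [g for g in result.summary["group"].unique() if g != "Total"] + ["Total"]
    width = max(len(g) for g in groups) + 2
    lines = ["Deviation summary (mean / SD / min / max)", ""]
    header = f"{'':28s}" + "".join(f"{g:>{width+6}s}" for g in groups)
    lines.append(header)
    ns = {g: int(result.summary.loc[result.summary['group'] == g, 'n'].iloc[0]) for g in groups}
    lines.append(f"{'Guided access cavity (n)':28s}" + "".join(f"{ns[g]:>{width+6}d}" for g in groups))
    metric_titles = {
        "coronal_mm": "Coronal linear deviation (mm)",
        "apical_mm": "Apical linear deviation (mm)",
        "angular_deg": "Angular deviation (deg)",
    }
    for metric in METRICS:
        if metric not in set(result.summary["metric"]):
            continue
        lines.append(metric_titles.get(metric, metric))
        sub = result.summary[result.summary["metric"] == metric].set_index("group")
        for stat in ("mean", "sd", "min", "max"):
            vals = "".join(f"{_fmt(sub.loc[g, stat], 2):>{width+6}s}" for g in groups)
            lines.append(f"  {stat:26s}" + vals)
    if result.roc:
        lines += ["", "Discrimination of canal inaccessibility (ROC)", ""]
        lines.append(f"{'metric':<16s}{'AUC':>8s}{'SE':>8s}{'p':>10s}")
        for metric, r in result.roc.items():
            lines.append(
                f"{metric:<16s}{_fmt(r.auc, 3):>8s}{_fmt(r.se, 3):>8s}{r.p_value:>10.2g}"
            )
    if sleeve is not None:
        depth = (
            drilling_depth_mm
            if drilling_depth_mm is not None
            else 16.0 - sleeve.height_mm
        )
        tol = sleeve_tolerance(sleeve, depth)
        lines += [
            "",
            "Sleeve intrinsic error",
            f"  bore {sleeve.inner_diameter_mm} mm / shank {sleeve.bur_diameter_mm} mm / height {sleeve.height_mm} mm",
            f"  clearance          {_fmt(tol.clearance_mm, 2)} mm",
            f"  max tilt           {_fmt(tol.max_angle_deg, 2)} deg",
            f"  max tip offset     {_fmt(tol.max_tip_offset_mm, 2)} mm at {_fmt(depth, 1)} mm beyond the sleeve",
        ]
    return "\n".join(lines) + "\n"
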