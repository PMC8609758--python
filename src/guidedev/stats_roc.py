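"""Statistical layer: group summaries, nonparametric tests and ROC analysis.

Reproduces the reporting structure of the accuracy study: per-group
mean/SD/min/max tables of the three deviation metrics, an omnibus
Kruskal–Wallis test with pairwise Mann–Whitney post-hoc comparisons
(Bonferroni-adjusted, capped at 1), n-weighted pooled means, and empirical
ROC curves scoring each deviation metric as a predictor of canal
*inaccessibility* (higher deviation = more positive).

The AUC is the trapezoidal area of the empirical curve and equals the
Mann–Whitney U statistic normalised by the product of the class sizes,
with ties counted one half — midranks are used everywhere so this
identity is exact.  The AUC standard error uses the Hanley–McNeil
formula, and the p-value tests AUC = 0.5 with a two-sided normal
statistic; a seeded permutation test is available as a robustness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedROCError

__all__ = [
    "METRICS",
    "GroupSummary",
    "ROCResult",
    "group_summary",
    "pooled_mean",
    "kruskal_wallis",
    "pairwise_mannwhitney",
    "roc_curve",
    "mann_whitney_auc",
    "auc_permutation_pvalue",
    "analyze_study",
    "AnalysisResult",
    "write_analysis",
]

#: Deviation metrics in reporting order.
METRICS = ("coronal_mm", "apical_mm", "angular_deg")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics of one metric."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


def group_summary(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    group_col: str = "group",
    groups: Sequence[str] | None = None,
    total_label: str = "Total",
) -> pd.DataFrame:
    """Tidy summary table: one row per (metric, group) plus a pooled row.

    Sample SD uses the n-1 denominator; a single-observation group reports
    SD 0.  Values are kept at full precision — rounding is report-time.
    """
    if groups is None:
        groups = list(dict.fromkeys(table[group_col]))
    rows = []
    for metric in metrics:
        for g in list(groups) + [total_label]:
            vals = table[metric] if g == total_label else table.loc[table[group_col] == g, metric]
            vals = np.asarray(vals, dtype=float)
            if len(vals) == 0:
                raise ValueError(f"group {g!r} has no records")
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": int(len(vals)),
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                }
            )
    return pd.DataFrame(rows)


def pooled_mean(group_means: Sequence[float], group_ns: Sequence[int]) -> float:
    """n-weighted mean of group means: ``sum(n_i m_i) / sum(n_i)``."""
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if means.shape != ns.shape or means.ndim != 1 or len(means) == 0:
        raise ValueError("group_means and group_ns must be equal-length 1-D sequences")
    if np.any(ns < 1):
        raise ValueError("all group sizes must be >= 1")
    return float(np.sum(means * ns) / np.sum(ns))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (midranks, tie-corrected) and chi-square p-value.

    All values identical across all groups is a legal degenerate input and
    returns ``(0.0, 1.0)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 1 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def _mannwhitney_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midranks, tie-corrected normal approximation)."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_mannwhitney(
    groups: Mapping[str, np.ndarray], correction: str = "bonferroni"
) -> pd.DataFrame:
    """All pairwise two-sided Mann–Whitney comparisons with multiplicity control.

    Returns a tidy DataFrame (group1, group2, U, p_raw, p_adj); the
    Bonferroni adjustment multiplies by the number of pairs and caps at 1,
    so equivalent samples report an adjusted p of exactly 1.00.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        U, p = _mannwhitney_pair(np.asarray(groups[a], float), np.asarray(groups[b], float))
        p_adj = min(p * m, 1.0) if correction == "bonferroni" else p
        rows.append({"group1": a, "group2": b, "U": U, "p_raw": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with AUC, Hanley–McNeil SE and normal p-value."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se: float
    p_value: float
    positive_label: str
    n_pos: int
    n_neg: int


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_label: str = "inaccessible",
) -> ROCResult:
    """Empirical ROC of ``scores`` against boolean ``labels`` (True = positive).

    Higher score means more positive.  The curve runs over all distinct
    thresholds from (0,0) to (1,1); the AUC is its trapezoidal area.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            f"ROC undefined: need both classes, got {n_pos} positive / {n_neg} negative"
        )

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    # keep the last index of each tie block
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]

    auc = float(np.trapezoid(tpr, fpr))
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        se=se,
        p_value=p,
        positive_label=positive_label,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC via the rank (Mann–Whitney U) route, ties counted one half.

    Equals ``roc_curve(...).auc`` exactly; kept separate because the
    identity is asserted, not assumed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("both classes required")
    ranks = sps.rankdata(s)
    U = float(ranks[y].sum() - n_pos * (n_pos + 1) / 2.0)
    return U / (n_pos * n_neg)


def auc_permutation_pvalue(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_permutations: int = 10000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided permutation p-value for AUC = 0.5 (label shuffling, seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(labels, dtype=bool)
    observed = abs(mann_whitney_auc(scores, y) - 0.5)
    hits = 0
    perm = y.copy()
    for _ in range(int(n_permutations)):
        rng.shuffle(perm)
        if abs(mann_whitney_auc(scores, perm) - 0.5) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# study-level analysis


@dataclass
class AnalysisResult:
    """All statistics of one study table."""

    summary: pd.DataFrame
    omnibus: pd.DataFrame  # metric, H, p
    pairwise: pd.DataFrame  # metric, group1, group2, U, p_raw, p_adj
    roc: dict[str, ROCResult]
    counts: pd.DataFrame  # group, n, n_inaccessible
    warnings: list[str]


def analyze_study(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    groups: Sequence[str] | None = None,
) -> AnalysisResult:
    """Run the full statistical layer on a per-case deviation table.

    ``table`` needs columns ``group``, the metric columns and (for ROC) a
    boolean ``accessible`` column.  A single-class accessibility column
    skips ROC with a warning rather than failing the run.
    """
    if groups is None:
        groups = list(dict.fromkeys(table["group"]))
    warnings: list[str] = []
    summary = group_summary(table, metrics=metrics, groups=groups)

    omni_rows = []
    pair_frames = []
    for metric in metrics:
        arrays = {g: table.loc[table["group"] == g, metric].to_numpy() for g in groups}
        if len(groups) >= 2:
            H, p = kruskal_wallis(list(arrays.values()))
            omni_rows.append({"metric": metric, "H": H, "p": p})
            pw = pairwise_mannwhitney(arrays)
            pw.insert(0, "metric", metric)
            pair_frames.append(pw)
    omnibus = pd.DataFrame(omni_rows)
    pairwise = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()

    roc: dict[str, ROCResult] = {}
    if "accessible" in table.columns:
        inaccessible = ~table["accessible"].astype(bool).to_numpy()
        for metric in metrics:
            try:
                roc[metric] = roc_curve(table[metric].to_numpy(), inaccessible)
            except UndefinedROCError as err:
                warnings.append(f"ROC skipped for {metric}: {err}")
    else:
        warnings.append("no accessibility labels; ROC stage skipped")

    if "accessible" in table.columns:
        counts = (
            table.assign(inaccessible=~table["accessible"].astype(bool))
            .groupby("group", sort=False)
            .agg(n=("group", "size"), n_inaccessible=("inaccessible", "sum"))
            .reset_index()
        )
    else:
        counts = table.groupby("group", sort=False).agg(n=("group", "size")).reset_index()
    return AnalysisResult(
        summary=summary,
        omnibus=omnibus,
        pairwise=pairwise,
        roc=roc,
        counts=counts,
        warnings=warnings,
    )


def write_analysis(result: AnalysisResult, directory: str | Path) -> dict[str, Path]:
    """Write summary.csv, pairwise.csv, roc.csv and summary.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    out["summary"] = directory / "summary.csv"
    result.summary.to_csv(out["summary"], index=False)
    out["pairwise"] = directory / "pairwise.csv"
    result.pairwise.to_csv(out["pairwise"], index=False)

    roc_rows = []
    for metric, r in result.roc.items():
        for f, t, th in zip(r.fpr, r.tpr, r.thresholds):
            roc_rows.append({"metric": metric, "fpr": f, "tpr": t, "threshold": th})
    out["roc"] = directory / "roc.csv"
    pd.DataFrame(roc_rows, columns=["metric", "fpr", "tpr", "threshold"]).to_csv(
        out["roc"], index=False
    )

    payload = {
        "auc": {m: r.auc for m, r in result.roc.items()},
        "auc_se": {m: r.se for m, r in result.roc.items()},
        "auc_p": {m: r.p_value for m, r in result.roc.items()},
        "kruskal_wallis": {
            row["metric"]: {"H": row["H"], "p": row["p"]} for _, row in result.omnibus.iterrows()
        },
        "pairwise": result.pairwise.to_dict(orient="records"),
        "counts": result.counts.to_dict(orient="records"),
        "warnings": result.warnings,
    }
    out["summary_json"] = directory / "summary.json"
    out["summary_json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out


def plot_roc(result: AnalysisResult, path: str | Path) -> None:
    """Optional ROC figure (one curve per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for metric, r in result.roc.items():
        ax.plot(r.fpr, r.tpr, label=f"{metric} (AUC = {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("Discrimination of canal inaccessibility")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
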