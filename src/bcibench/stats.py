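"""Rank-based statistical comparison of classifiers across subjects.

Given a subjects x classifiers performance table (accuracy or AUC), each
subject's classifiers are ranked (rank 1 = best, ties averaged), and the
Friedman test asks whether the average ranks could have arisen by chance:

    chi2 = 12 N / (k (k+1)) * (sum_j R_j^2 - k (k+1)^2 / 4),   df = k - 1,

with N subjects, k classifiers and R_j the average rank of classifier j (the
classic statistic, no tie correction).  When the null is rejected, the Holm
step-down procedure compares every classifier against the control (the one
with the best average rank) using

    z_j = (R_j - R_control) / sqrt(k (k+1) / (6 N)),

two-sided normal p-values sorted ascending and tested against alpha/(k-i).
Classifiers never shown worse than the control form the "recommended" set.

Reporting helpers truncate average ranks to 2 and p-values to 4 decimals;
the core API always returns full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "PerformanceTable",
    "RankTable",
    "FriedmanResult",
    "HolmComparison",
    "HolmResult",
    "rank_table",
    "friedman",
    "holm_posthoc",
    "recommended_set",
    "truncate",
    "compare_classifiers",
    "load_performance_csv",
    "load_benchmark_table",
    "BENCHMARK_TABLES",
]

#: Bundled fixture tables: published per-subject test performance of the seven
#: benchmarked classifiers (21 synchronous subjects scored by accuracy, 8
#: self-paced subjects scored by AUC; one table per feature family).
BENCHMARK_TABLES = (
    "synchronous_bp",
    "synchronous_morlet",
    "selfpaced_bp",
    "selfpaced_morlet",
)


@dataclass
class PerformanceTable:
    """Subjects x classifiers scores; higher is better."""

    scores: np.ndarray
    subject_ids: list[str]
    classifier_ids: list[str]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (subjects x classifiers)")
        n, k = self.scores.shape
        if n != len(self.subject_ids) or k != len(self.classifier_ids):
            raise ValueError("score matrix does not match id lists")
        if k < 2:
            raise ValueError("need >= 2 classifiers to compare")
        if n < 2:
            raise ValueError("need >= 2 subjects to compare")
        if np.any(np.isnan(self.scores)):
            raise ValueError("performance table contains missing cells")


@dataclass
class RankTable:
    ranks: np.ndarray
    average_ranks: np.ndarray
    classifier_ids: list[str]
    n_subjects: int
    n_classifiers: int

    def control(self) -> int:
        """Index of the control classifier (best, i.e. smallest, average rank)."""
        return int(np.argmin(self.average_ranks))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class HolmComparison:
    classifier: str
    z: float
    p_value: float
    threshold: float
    rejected: bool


@dataclass
class HolmResult:
    control: str
    comparisons: list[HolmComparison]  # sorted by ascending p-value
    alpha: float


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (reporting convention)."""
    f = 10.0**decimals
    return math.trunc(x * f) / f


def rank_table(perf: PerformanceTable) -> RankTable:
    """Per-subject ranks (1 = best score, ties get the mean of spanned positions)."""
    sign = -1.0 if perf.higher_is_better else 1.0
    ranks = np.vstack([sst.rankdata(sign * row, method="average") for row in perf.scores])
    return RankTable(
        ranks=ranks,
        average_ranks=ranks.mean(axis=0),
        classifier_ids=list(perf.classifier_ids),
        n_subjects=perf.scores.shape[0],
        n_classifiers=perf.scores.shape[1],
    )


def friedman(ranks: RankTable) -> FriedmanResult:
    """Classic Friedman chi-square on average ranks (no tie correction)."""
    N, k = ranks.n_subjects, ranks.n_classifiers
    if N < 2 or k < 2:
        raise ValueError("Friedman test needs >= 2 subjects and >= 2 classifiers")
    R = ranks.average_ranks
    chi2 = (12.0 * N / (k * (k + 1))) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return FriedmanResult(chi2=float(chi2), df=df, p_value=float(sst.chi2.sf(chi2, df)))


def holm_posthoc(ranks: RankTable, alpha: float = 0.1) -> HolmResult:
    """Holm step-down comparisons of every classifier against the control.

    Raw two-sided normal p-values are sorted ascending and rejected
    sequentially while ``p_(i) < alpha / (k - i)``; the first non-rejection
    stops the procedure.
    """
    N, k = ranks.n_subjects, ranks.n_classifiers
    if k < 2:
        raise ValueError("Holm post-hoc needs >= 2 classifiers")
    ctrl = ranks.control()
    se = math.sqrt(k * (k + 1) / (6.0 * N))
    rows = []
    for j in range(k):
        if j == ctrl:
            continue
        z = (ranks.average_ranks[j] - ranks.average_ranks[ctrl]) / se
        p = 2.0 * sst.norm.sf(abs(z))
        rows.append((ranks.classifier_ids[j], float(z), float(p)))
    rows.sort(key=lambda r: r[2])

    comparisons = []
    still_rejecting = True
    for i, (cid, z, p) in enumerate(rows, start=1):
        threshold = alpha / (k - i)
        rejected = still_rejecting and p < threshold
        if not rejected:
            still_rejecting = False
        comparisons.append(
            HolmComparison(classifier=cid, z=z, p_value=p, threshold=threshold, rejected=rejected)
        )
    return HolmResult(control=ranks.classifier_ids[ctrl], comparisons=comparisons, alpha=alpha)


def recommended_set(holm: HolmResult) -> dict[str, list[str]]:
    """Partition classifiers: the control plus every non-rejected comparison is
    recommended; classifiers shown significantly worse are not."""
    recommended = [holm.control] + [c.classifier for c in holm.comparisons if not c.rejected]
    not_recommended = [c.classifier for c in holm.comparisons if c.rejected]
    return {"recommended": recommended, "not_recommended": not_recommended}


# ---------------------------------------------------------------------------
# CSV interface and the bundled benchmark fixtures.


def load_performance_csv(path: str | Path) -> PerformanceTable:
    """Read a performance CSV: first column subject id, remaining columns scores."""
    df = pd.read_csv(path)
    return PerformanceTable(
        scores=df.iloc[:, 1:].to_numpy(dtype=float),
        subject_ids=[str(s) for s in df.iloc[:, 0]],
        classifier_ids=[str(c) for c in df.columns[1:]],
    )


def load_benchmark_table(name: str) -> PerformanceTable:
    """Load one of the bundled reference tables (see :data:`BENCHMARK_TABLES`)."""
    if name not in BENCHMARK_TABLES:
        raise ValueError(f"unknown benchmark table {name!r}; options: {BENCHMARK_TABLES}")
    ref = resources.files("bcibench.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return load_performance_csv(path)


def compare_classifiers(perf: PerformanceTable, alpha: float = 0.1) -> dict:
    """Full comparison: ranks -> Friedman -> Holm -> recommended set.

    Returns a JSON-serialisable report.  Ranks and p-values appear both at full
    precision and truncated (2 / 4 decimals) for tabular display.
    """
    rt = rank_table(perf)
    fr = friedman(rt)
    hm = holm_posthoc(rt, alpha=alpha)
    rec = recommended_set(hm)
    return {
        "n_subjects": rt.n_subjects,
        "n_classifiers": rt.n_classifiers,
        "alpha": alpha,
        "average_ranks": {
            cid: {"rank": float(r), "display": truncate(float(r), 2)}
            for cid, r in zip(rt.classifier_ids, rt.average_ranks)
        },
        "friedman": {"chi2": fr.chi2, "df": fr.df, "p": fr.p_value},
        "control": hm.control,
        "holm": [
            {
                "pair": f"{c.classifier} vs. {hm.control}",
                "z": c.z,
                "p": c.p_value,
                "p_display": truncate(c.p_value, 4),
                "threshold": c.threshold,
                "rejected": c.rejected,
            }
            for c in hm.comparisons
        ],
        **rec,
    }


def report_text(report: dict) -> str:
    """Human-readable rendering of a :func:`compare_classifiers` report."""
    lines = []
    lines.append(
        f"Classifier comparison over {report['n_subjects']} subjects, "
        f"{report['n_classifiers']} classifiers (alpha = {report['alpha']})"
    )
    lines.append("")
    lines.append("Average ranks (1 = best):")
    ordered = sorted(report["average_ranks"].items(), key=lambda kv: kv[1]["rank"])
    for cid, info in ordered:
        lines.append(f"  {cid:<10s} {info['display']:.2f}")
    fr = report["friedman"]
    lines.append("")
    lines.append(f"Friedman chi2 = {fr['chi2']:.4f} (df = {fr['df']}), p = {fr['p']:.3g}")
    lines.append(f"Control classifier: {report['control']}")
    lines.append("")
    lines.append("Holm step-down comparisons vs. control:")
    for c in report["holm"]:
        flag = "rejected" if c["rejected"] else "retained"
        lines.append(
            f"  {c['pair']:<18s} p = {c['p_display']:.4f}  "
            f"(threshold {c['threshold']:.4f}, {flag})"
        )
    lines.append("")
    lines.append("Recommended: " + ", ".join(report["recommended"]))
    lines.append("Not recommended: " + (", ".join(report["not_recommended"]) or "(none)"))
    return "\n".join(lines)


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2)
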