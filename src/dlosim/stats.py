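"""Cohort-level study statistics and report generation.

Reproduces the statistical battery of the planning study on a synthetic
cohort: per-procedure summaries of the planned length changes, the
proportion of symptomatic changes (|delta total| > 6 mm) compared across
the four matched procedures with the Cochran Q test, exact McNemar
pairwise follow-ups with Bonferroni correction, Pearson correlation of
pre-operative HKA with the total length change per procedure, and
paired t-tests of pre vs planned segment lengths.

The Cochran Q statistic is computed from its textbook formula

    Q = k (k - 1) * sum_j (C_j - Cbar)^2 / (k * sum_i R_i - sum_i R_i^2)

with df = k - 1 and the p-value from the chi-square distribution;
subjects with all-equal rows contribute nothing.  A degenerate matrix
(every row constant, denominator zero) is reported as Q = 0, p = 1 with
the ``degenerate`` flag set.  The pairwise follow-up is the exact
(binomial) McNemar test on the discordant counts, Bonferroni-adjusted
by the number of pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StudyConfig
from .cohort import CohortParams, sample_cohort
from .geometry import ValidationError, measure_all
from .planner import PROCEDURES, plan_all

__all__ = [
    "TTestResult",
    "CochranQResult",
    "StudyResult",
    "paired_t",
    "cochran_q",
    "pairwise_mcnemar_bonferroni",
    "pearson_r",
    "run_study",
]


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


class CochranQResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    degenerate: bool = False


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TTestResult:
    """Classical paired t-test on post - pre differences (two-sided).

    Equal pre/post return t = 0, p = 1.  A nonzero but constant
    difference has zero variance: the statistic is infinite and the
    p-value NaN, with the ``degenerate`` flag set.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValidationError("paired_t needs two equal-length 1-D samples of size >= 2")
    d = post - pre
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, mean), float("nan"), degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TTestResult(float(t), p)


def _check_binary(matrix) -> np.ndarray:
    x = np.asarray(matrix)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 2:
        raise ValidationError("need an n x k matrix with k >= 2 treatments")
    if not np.isin(x, (0, 1)).all():
        raise ValidationError("matrix entries must be 0 or 1")
    return x.astype(int)


def cochran_q(matrix) -> CochranQResult:
    """Cochran Q test for equality of k matched proportions (binary n x k matrix)."""
    x = _check_binary(matrix)
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    num = k * (k - 1) * float(np.sum((col - col.mean()) ** 2))
    denom = float(k * row.sum() - np.sum(row**2))
    df = k - 1
    if denom == 0.0:
        return CochranQResult(0.0, df, 1.0, degenerate=True)
    q = num / denom
    p = float(sps.chi2.sf(q, df))
    return CochranQResult(q, df, p)


def pairwise_mcnemar_bonferroni(
    matrix, labels: Optional[Sequence[str]] = None
) -> list[dict]:
    """Exact McNemar test for every column pair, Bonferroni-adjusted.

    Returns one record per pair with the discordant counts, the raw
    exact binomial p-value and the adjusted p = min(1, m * raw) where m
    is the number of pairs.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    x = _check_binary(matrix)
    k = x.shape[1]
    if labels is None:
        labels = [f"col{j}" for j in range(k)]
    if len(labels) != k:
        raise ValidationError("labels must match the number of columns")
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        a = int(np.sum((x[:, i] == 1) & (x[:, j] == 1)))
        b = int(np.sum((x[:, i] == 1) & (x[:, j] == 0)))
        c = int(np.sum((x[:, i] == 0) & (x[:, j] == 1)))
        d = int(np.sum((x[:, i] == 0) & (x[:, j] == 0)))
        if b + c == 0:
            raw = 1.0
        else:
            raw = float(mcnemar([[a, b], [c, d]], exact=True).pvalue)
        out.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "discordant": [b, c],
                "p_raw": raw,
                "p_adjusted": min(1.0, m * raw),
            }
        )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length 1-D samples of size >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("pearson_r is undefined for a constant sample")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# study orchestration


@dataclass(frozen=True)
class StudyResult:
    """Aggregated study output; see :func:`run_study`."""

    n: int
    seed: int
    procedures: dict          # per procedure: delta stats, symptomatic k/n, tests
    cochran: CochranQResult
    pairwise: list[dict]
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "procedures": self.procedures,
            "cochran_q": {
                "statistic": self.cochran.statistic,
                "df": self.cochran.df,
                "pvalue": self.cochran.pvalue,
                "degenerate": self.cochran.degenerate,
            },
            "pairwise_mcnemar": self.pairwise,
            "provenance": self.provenance,
        }


def _delta_stats(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def run_study(
    params: CohortParams,
    config: Optional[StudyConfig] = None,
    outdir: Optional[str | Path] = None,
    make_figure: bool = True,
) -> StudyResult:
    """Generate a cohort, plan all four procedures on every limb, and analyse.

    Deterministic under ``params.seed``.  When ``outdir`` is given the
    report files are written there: the cohort landmark table and its
    provenance sidecar, the measures and plans tables, the study JSON, a
    histogram figure of the total length change per procedure, and a log
    of solver residuals.
    """
    config = (config or StudyConfig()).validate()
    params = params.validate()
    if params.n <= 0:
        raise ValidationError("run_study requires a cohort of n >= 1 limbs")

    limbs, provenance = sample_cohort(params)
    all_plans = [plan_all(limb, config) for limb in limbs]

    measures_rows = []
    plan_rows = []
    residual_rows = []
    for i, (limb, plans) in enumerate(zip(limbs, all_plans)):
        m = measure_all(limb)
        measures_rows.append({"limb_id": i, **m.as_dict()})
        for plan in plans:
            plan_rows.append(
                {
                    "limb_id": i,
                    "procedure": plan.procedure,
                    "dfo_angle_deg": plan.dfo.correction_deg,
                    "hto_angle_deg": plan.hto.correction_deg,
                    "delta_femur_mm": plan.delta_femur_mm,
                    "delta_tibia_mm": plan.delta_tibia_mm,
                    "delta_total_mm": plan.delta_total_mm,
                    "symptomatic": plan.symptomatic,
                }
            )
            residual_rows.append(
                {
                    "limb_id": i,
                    "procedure": plan.procedure,
                    "mldfa_residual_deg": abs(plan.post.mldfa_deg - config.mldfa_target_deg),
                    "wbl_residual_pct": abs(plan.post.wbl_ratio_pct - config.wbl_target_pct),
                }
            )
    measures_df = pd.DataFrame(measures_rows)
    plans_df = pd.DataFrame(plan_rows)
    residuals_df = pd.DataFrame(residual_rows)

    n = params.n
    sympt = np.zeros((n, len(PROCEDURES)), dtype=int)
    proc_results: dict[str, dict] = {}
    for j, proc in enumerate(PROCEDURES):
        plans = [all_plans[i][j] for i in range(n)]
        d_femur = np.array([p.delta_femur_mm for p in plans])
        d_tibia = np.array([p.delta_tibia_mm for p in plans])
        d_total = np.array([p.delta_total_mm for p in plans])
        sympt[:, j] = [p.symptomatic for p in plans]
        k = int(sympt[:, j].sum())
        entry: dict = {
            "delta_femur_mm": _delta_stats(d_femur),
            "delta_tibia_mm": _delta_stats(d_tibia),
            "delta_total_mm": _delta_stats(d_total),
            "symptomatic": {"count": k, "n": n, "proportion": k / n, "label": f"{k}/{n}"},
        }
        if n >= 3:
            pre_hka = np.array([p.pre.hka_deg for p in plans])
            r, p_r = pearson_r(pre_hka, d_total)
            entry["pearson_hka_vs_delta_total"] = {"r": r, "p": p_r}
            for seg in ("femur", "tibia", "total"):
                pre_len = np.array([getattr(p.pre, f"{seg}_len_mm") for p in plans])
                post_len = np.array([getattr(p.post, f"{seg}_len_mm") for p in plans])
                tt = paired_t(pre_len, post_len)
                entry[f"paired_t_{seg}"] = {
                    "t": tt.statistic,
                    "p": tt.pvalue,
                    "degenerate": tt.degenerate,
                }
        proc_results[proc] = entry

    q = cochran_q(sympt)
    pairwise = pairwise_mcnemar_bonferroni(sympt, labels=list(PROCEDURES))

    result = StudyResult(
        n=n,
        seed=params.seed,
        procedures=proc_results,
        cochran=q,
        pairwise=pairwise,
        provenance=provenance,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_landmark_csv

        write_landmark_csv(outdir / "cohort.csv", limbs)
        (outdir / "cohort.json").write_text(json.dumps(provenance, sort_keys=True, indent=1))
        measures_df.to_csv(outdir / "measures.csv", index=False, float_format="%.10g")
        plans_df.to_csv(outdir / "plans.csv", index=False, float_format="%.10g")
        residuals_df.to_csv(outdir / "solver_residuals.csv", index=False, float_format="%.6g")
        (outdir / "study.json").write_text(
            json.dumps(result.to_json_dict(), sort_keys=True, indent=1)
        )
        if make_figure:
            _plot_delta_histograms(plans_df, outdir / "delta_histograms.png")

    return result


def _plot_delta_histograms(plans_df: pd.DataFrame, path: Path) -> None:
    """2x2 panel of 1-mm-binned histograms of the total length change."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = np.arange(-10, 26, 1)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, proc in zip(axes.ravel(), PROCEDURES):
        vals = plans_df.loc[plans_df["procedure"] == proc, "delta_total_mm"]
        ax.hist(vals, bins=bins, edgecolor="black")
        ax.axvline(6, color="red", linestyle="--", linewidth=0.8)
        ax.axvline(-6, color="red", linestyle="--", linewidth=0.8)
        ax.set_title(proc, fontsize=10)
        ax.set_xlabel("delta total leg length (mm)")
        ax.set_ylabel("knees")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
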