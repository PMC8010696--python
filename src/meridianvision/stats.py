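"""Meridional-disparity statistics: per-eye strong-minus-weak differences,
t contrasts with Bonferroni adjustment, Pearson correlations, and the
group-by-metric disparity report (strong mean, weak mean, difference, t, p)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class DisparityRecord:
    """One eye's strong/weak values for one metric."""

    eye_id: str
    group: str
    metric: str
    strong_value: float
    weak_value: float
    subject_id: str | None = None

    @property
    def disparity(self) -> float:
        return self.strong_value - self.weak_value


@dataclass(frozen=True)
class ContrastResult:
    mean_diff: float
    se: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    adjusted_p: float | None = None


def paired_contrast(disparities: Sequence[float]) -> ContrastResult:
    """One-sample t on per-eye disparities: t = mean/SE, df = n - 1."""
    d = np.asarray(disparities, float)
    if d.size < 3:
        raise ValueError("need at least 3 eyes")
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    if se == 0.0:
        t = 0.0 if mean == 0.0 else np.copysign(np.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / se
        p = 2.0 * float(sstats.t.sf(abs(t), df))
    return ContrastResult(mean, se, float(t), df, p)


def group_contrast(disparities_a: Sequence[float],
                   disparities_b: Sequence[float]) -> ContrastResult:
    """Pooled-variance two-sample t between groups' disparities, df = n1+n2-2."""
    a = np.asarray(disparities_a, float)
    b = np.asarray(disparities_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 eyes")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = sstats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))
    return ContrastResult(float(a.mean() - b.mean()), se,
                          float(res.statistic), df, float(res.pvalue))


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def bonferroni(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) for a family of ``m`` comparisons."""
    p = np.asarray(p_values, float)
    if m < p.size:
        raise ValueError("family size m must cover all p values")
    return np.minimum(1.0, p * m)


def one_eye_per_subject(records: Sequence[DisparityRecord],
                        rng: np.random.Generator) -> list:
    """Keep one randomly chosen eye per subject (subject-level sensitivity
    mode); records without a subject id are kept as independent eyes."""
    by_subject: dict = {}
    singles = []
    for rec in records:
        if rec.subject_id is None:
            singles.append(rec)
        else:
            by_subject.setdefault((rec.subject_id, rec.metric), []).append(rec)
    chosen = [recs[rng.integers(len(recs))] for recs in by_subject.values()]
    return singles + chosen


def build_disparity_report(records: Sequence[DisparityRecord],
                           bonferroni_within_group: bool = True) -> pd.DataFrame:
    """Per group x metric summary table (the strong/weak/difference layout).

    Columns: group, metric, n, strong/weak/difference means and SEs, t, df, p
    and (optionally) the Bonferroni-adjusted p over each group's metric family.
    """
    if not records:
        raise ValueError("no disparity records")
    df = pd.DataFrame([{
        "eye_id": r.eye_id, "group": r.group, "metric": r.metric,
        "strong": r.strong_value, "weak": r.weak_value,
        "difference": r.disparity,
    } for r in records])
    rows = []
    for (group, metric), sub in df.groupby(["group", "metric"], sort=False):
        if sub.empty:
            raise ValueError(f"empty cell {group}/{metric}")
        n = len(sub)
        if n >= 3:
            contrast = paired_contrast(sub["difference"].to_numpy())
            diff_mean, diff_se = contrast.mean_diff, contrast.se
            t, df_, p = (contrast.t_statistic, contrast.degrees_of_freedom,
                         contrast.p_value)
        else:  # too few eyes for inference; keep the descriptive columns
            diff_mean = sub["difference"].mean()
            diff_se = (sub["difference"].std(ddof=1) / np.sqrt(n)
                       if n > 1 else np.nan)
            t, df_, p = np.nan, n - 1, np.nan
        rows.append({
            "group": group, "metric": metric, "n": n,
            "strong_mean": sub["strong"].mean(),
            "strong_se": sub["strong"].std(ddof=1) / np.sqrt(n),
            "weak_mean": sub["weak"].mean(),
            "weak_se": sub["weak"].std(ddof=1) / np.sqrt(n),
            "diff_mean": diff_mean,
            "diff_se": diff_se,
            "t": t,
            "df": df_,
            "p": p,
        })
    report = pd.DataFrame(rows)
    if bonferroni_within_group:
        report["p_bonferroni"] = np.nan
        for group, sub in report.groupby("group", sort=False):
            report.loc[sub.index, "p_bonferroni"] = bonferroni(
                sub["p"].to_numpy(), len(sub))
    return report


def format_report(report: pd.DataFrame) -> str:
    """Human-readable text rendering with the strong/weak/difference columns."""
    lines = []
    for group, sub in report.groupby("group", sort=False):
        lines.append(f"{group} group")
        lines.append(f"  {'Metric':<18}{'Strong meridian':>18}"
                     f"{'Weak meridian':>18}{'Difference':>18}"
                     f"{'t':>9}{'p':>10}")
        for _, row in sub.iterrows():
            lines.append(
                f"  {row['metric']:<18}"
                f"{row['strong_mean']:>10.3f} ± {row['strong_se']:<5.3f}"
                f"{row['weak_mean']:>10.3f} ± {row['weak_se']:<5.3f}"
                f"{row['diff_mean']:>10.3f} ± {row['diff_se']:<5.3f}"
                f"{row['t']:>9.3f}{row['p']:>10.4f}")
        lines.append("")
    return "\n".join(lines)
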