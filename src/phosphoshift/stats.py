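"""Group comparisons with post-hoc power gating and the cohort report.

Comparisons use a paired t-test (within-patient compartment pairs), a
Welch t-test (independent groups with ≥ 5 observations per arm) or the
Mann–Whitney U test (smaller arms; exact null distribution for small
samples).  A comparison is flagged significant only when both gates pass:
"*" for p < 0.05 and "**" for p < 0.001, each additionally requiring
post-hoc power > 0.8 computed from the observed effect size.  Post-hoc
power is descriptive, not inferential; with the small group sizes the
study emulates (e.g. n = 2 LGG patients) it deliberately blocks flagging.
No multiple-testing correction is applied by default (raw p-values are
reported per comparison); a Holm option exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower, TTestPower

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "power_check",
    "cohort_report",
    "METRICS",
]

#: metrics the cohort report covers
METRICS = ["d_pi", "d_gamma", "d_alpha", "d_beta", "ph", "mg", "ion"]

_FLAG_NONE = "none"


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    test: str                  # paired_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    effect_size: float         # Cohen's d (d_z for paired)
    power: float = np.nan
    flagged: str = _FLAG_NONE  # none | "*" | "**"

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _choose_test(n_a: int, n_b: int, paired: bool) -> str:
    if paired:
        return "paired_t"
    if min(n_a, n_b) >= 5:
        return "welch_t"
    return "mann_whitney"


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf
    return float((np.mean(a) - np.mean(b)) / pooled)


def compare_groups(
    a,
    b,
    paired: bool = False,
    test: str = "auto",
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided comparison of two observation vectors.

    ``test="auto"`` applies the rule: paired t for paired designs, Welch t
    for independent groups with ≥ 5 per arm, Mann–Whitney otherwise (exact
    null distribution when min(n) ≤ 8).  The result carries post-hoc power
    and the significance flag gated on it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires aligned, equal-length groups")
    if test == "auto":
        test = _choose_test(len(a), len(b), paired)

    if test == "paired_t":
        diff = a - b
        sd = np.std(diff, ddof=1)
        if sd == 0:
            md = float(np.mean(diff))
            stat = 0.0 if md == 0 else np.inf * np.sign(md)
            p = 1.0 if md == 0 else 0.0
            if md != 0:
                warnings.warn(
                    "paired t-test with zero variance and nonzero mean "
                    "difference: p reported from the degenerate limit",
                    RuntimeWarning,
                )
            eff = 0.0 if md == 0 else np.inf
        else:
            stat, p = sps.ttest_rel(a, b)
            eff = float(np.mean(diff) / sd)
    elif test == "welch_t":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        eff = _cohens_d(a, b)
    elif test == "mann_whitney":
        method = "exact" if min(len(a), len(b)) <= 8 else "auto"
        u = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = u.statistic, u.pvalue
        eff = _cohens_d(a, b)
    else:
        raise ValueError(f"unknown test: {test!r}")

    result = ComparisonResult(
        metric=metric, group_a=group_a, group_b=group_b, test=test,
        statistic=float(stat), p_value=float(p),
        n_a=len(a), n_b=len(b), effect_size=eff,
    )
    result.power = power_check(result, alpha=alpha)
    result.flagged = _flag(result.p_value, result.power)
    return result


def _flag(p: float, power: float) -> str:
    if power > 0.8 and p < 0.001:
        return "**"
    if power > 0.8 and p < 0.05:
        return "*"
    return _FLAG_NONE


def power_check(result: ComparisonResult, alpha: float = 0.05) -> float:
    """Post-hoc power at ``alpha`` from the observed effect size.

    Noncentral-t power for the t tests; normal approximation of the U
    statistic for Mann–Whitney (P(X>Y) = Φ(d/√2) under a normal shift).
    Monotone increasing in |effect| and in n; equals ``alpha`` at zero
    observed effect for the t tests.
    """
    d = abs(result.effect_size)
    if not np.isfinite(d):
        return 1.0
    if result.test == "paired_t":
        p = float(TTestPower().power(d, nobs=result.n_a, alpha=alpha, alternative="two-sided"))
        return p if np.isfinite(p) else 1.0  # noncentral t overflows at huge d
    if result.test == "welch_t":
        p = float(TTestIndPower().power(
            d, nobs1=result.n_a, ratio=result.n_b / result.n_a,
            alpha=alpha, alternative="two-sided",
        ))
        return p if np.isfinite(p) else 1.0
    if result.test == "mann_whitney":
        n1, n2 = result.n_a, result.n_b
        p1 = sps.norm.cdf(d / np.sqrt(2.0))
        mu0 = n1 * n2 / 2.0
        sd0 = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        shift = n1 * n2 * (p1 - 0.5)
        z = sps.norm.ppf(1 - alpha / 2)
        upper = 1 - sps.norm.cdf(z - shift / sd0)
        lower = sps.norm.cdf(-z - shift / sd0)
        return float(upper + lower)
    raise ValueError(f"unknown test: {result.test!r}")


# -- cohort-level report ---------------------------------------------------

def _summaries(grouped: dict[str, pd.DataFrame], metrics: list[str]) -> pd.DataFrame:
    rows = []
    for group, df in grouped.items():
        for metric in metrics:
            if metric not in df.columns or len(df) == 0:
                continue
            vals = df[metric].to_numpy(dtype=float)
            rows.append({
                "group": group, "metric": metric, "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "mean": float(np.mean(vals)),
            })
    return pd.DataFrame(rows)


_PAIRED = {("HGG-CE", "HGG-EDM")}  # within-patient compartment pair


def _pairwise(grouped: dict[str, pd.DataFrame], metrics: list[str]) -> list[ComparisonResult]:
    names = [g for g, df in grouped.items() if len(df) >= 2]
    out = []
    for metric in metrics:
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                da, db = grouped[ga], grouped[gb]
                if metric not in da.columns or metric not in db.columns:
                    continue
                paired = (ga, gb) in _PAIRED or (gb, ga) in _PAIRED
                if paired:
                    merged = da.merge(db, on="patient", suffixes=("_a", "_b"))
                    if len(merged) < 2:
                        continue
                    a = merged[f"{metric}_a"].to_numpy()
                    b = merged[f"{metric}_b"].to_numpy()
                else:
                    a = da[metric].to_numpy()
                    b = db[metric].to_numpy()
                try:
                    out.append(compare_groups(
                        a, b, paired=paired, metric=metric,
                        group_a=ga, group_b=gb,
                    ))
                except ValueError as exc:
                    logger.warning("comparison %s %s/%s skipped: %s", metric, ga, gb, exc)
    return out


def _boxplots(grouped: dict[str, pd.DataFrame], metrics: list[str], outdir) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    paths = []
    for metric in metrics:
        data = [
            (g, df[metric].dropna().to_numpy())
            for g, df in grouped.items()
            if metric in df.columns and len(df) > 0
        ]
        if not data:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.boxplot(
            [v for _, v in data], tick_labels=[g for g, _ in data],
            medianprops={"color": "red"},
        )
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = Path(outdir) / f"boxplot_{metric}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))
    return paths


def cohort_report(
    grouped: dict[str, pd.DataFrame],
    metrics: list[str] | None = None,
    outdir=None,
    holm: bool = False,
) -> dict:
    """Per-metric group summaries, all pairwise comparisons, and flags.

    Returns a bundle with ``summaries`` (DataFrame), ``comparisons``
    (DataFrame, one row per comparison) and the figure paths when
    ``outdir`` is given.  ``holm=True`` additionally reports Holm-adjusted
    p-values per metric family (flags still use raw p-values).
    """
    metrics = metrics or [m for m in METRICS if any(
        m in df.columns for df in grouped.values()
    )]
    summaries = _summaries(grouped, metrics)
    comparisons = _pairwise(grouped, metrics)
    comp_df = pd.DataFrame([asdict(c) for c in comparisons])
    if holm and len(comp_df):
        from statsmodels.stats.multitest import multipletests

        comp_df["p_holm"] = np.nan
        for metric in metrics:
            sel = comp_df["metric"] == metric
            if sel.sum():
                comp_df.loc[sel, "p_holm"] = multipletests(
                    comp_df.loc[sel, "p_value"], method="holm",
                )[1]
    bundle = {"summaries": summaries, "comparisons": comp_df}
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(outdir / "group_summaries.csv", index=False)
        comp_df.to_csv(outdir / "comparisons.csv", index=False)
        bundle["figures"] = _boxplots(grouped, metrics, outdir)
    return bundle
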