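"""Task-validation statistics with the effect sizes used in the analysis.

Non-parametric omnibus and one-sample tests for the ordinal distress and
valence ratings (Friedman's ANOVA with Kendall's W; Wilcoxon signed-rank with
r = Z / sqrt(N)), and parametric tests for the mean ratings (paired t with
Cohen's d; one-way repeated-measures ANOVA with partial eta squared and
FDR-controlled post hoc paired t-tests). All p values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "effect_size_r",
    "cohens_d_from_summary",
    "friedman_kendall",
    "wilcoxon_one_sample",
    "paired_t_cohend",
    "cohens_d_av",
    "rm_anova",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, df, two-tailed p and its effect size."""

    name: str
    statistic: float
    df: float | tuple | None
    p: float
    effect_size_name: str
    effect_size: float
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


def effect_size_r(z: float, n: int) -> float:
    """Wilcoxon effect size r = |Z| / sqrt(N) for a sample of size N."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(abs(z) / np.sqrt(n))


def cohens_d_from_summary(mean_x: float, sd_x: float, mean_y: float, sd_y: float) -> float:
    """Cohen's d from condition means and SDs (average-variance form)."""
    pooled = np.sqrt((sd_x**2 + sd_y**2) / 2)
    if pooled == 0:
        return 0.0
    return float((mean_x - mean_y) / pooled)


def friedman_kendall(data: np.ndarray | pd.DataFrame) -> TestResult:
    """Friedman's rank ANOVA across k repeated conditions, with Kendall's W.

    ``data`` is n subjects x k conditions. W = chi2 / (n * (k - 1)) is the
    concordance effect size; ties are handled by midranks.
    """
    arr = np.asarray(data, dtype=float)
    n, k = arr.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if k < 3:
        raise ValueError("need at least 3 conditions")
    if np.isnan(arr).any():
        raise ValueError("no missing cells allowed")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": arr.ravel(),
        }
    )
    res = pg.friedman(data=long, dv="value", within="condition", subject="subject")
    w = float(res["W"].iloc[0])
    if np.isnan(w):  # all rows fully tied: no concordance signal at all
        w = 0.0
    chi2 = w * n * (k - 1)  # tie-corrected statistic implied by Kendall's W
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult(
        name="friedman",
        statistic=chi2,
        df=k - 1,
        p=p,
        effect_size_name="kendall_w",
        effect_size=w,
    )


def wilcoxon_one_sample(values, hypothetical_median: float) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a hypothetical median.

    Uses the tie-corrected normal approximation; the effect size is
    r = |Z| / sqrt(N) with N the full sample size.
    """
    values = np.asarray(values, dtype=float)
    n_total = len(values)
    diffs = values - hypothetical_median
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise ValueError("all differences are zero")
    if len(nonzero) < 5:
        raise ValueError("need at least 5 nonzero differences")
    # one-sided call keeps the sign of Z (two-sided reports min-rank sums only)
    res = stats.wilcoxon(nonzero, correction=False, method="approx", alternative="greater")
    z = float(res.zstatistic)
    r = effect_size_r(z, n_total)
    return TestResult(
        name="wilcoxon_one_sample",
        statistic=z,
        df=None,
        p=float(2 * stats.norm.sf(abs(z))),
        effect_size_name="r",
        effect_size=float(r),
        extra={"n": n_total, "n_nonzero": len(nonzero)},
    )


def cohens_d_av(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d for paired data using the average of the two condition SDs."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    return cohens_d_from_summary(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))


def paired_t_cohend(x, y, level: float = 0.95) -> TestResult:
    """Paired-samples t test with Cohen's d and a CI on the mean difference."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    d = x - y
    if d.std(ddof=1) == 0 and not np.allclose(d, 0):
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    ci = res.confidence_interval(level)
    return TestResult(
        name="paired_t",
        statistic=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        effect_size_name="cohens_d",
        effect_size=cohens_d_av(x, y),
        ci=(float(ci.low), float(ci.high)),
    )


def rm_anova(data: np.ndarray | pd.DataFrame, posthoc: bool = True) -> TestResult:
    """One-way repeated-measures ANOVA with partial eta squared.

    ``data`` is n subjects x k conditions of per-subject means. Post hoc
    pairwise paired t-tests (Benjamini-Hochberg adjusted) are attached in
    ``extra['posthoc']``. No sphericity correction is applied.
    """
    arr = np.asarray(data, dtype=float)
    n, k = arr.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if np.isnan(arr).any():
        raise ValueError("complete data required")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": arr.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject", detailed=True,
        correction=False, effsize="np2",
    )
    row = aov.iloc[0]
    if "F" in aov.columns and np.isfinite(row.get("F", np.nan)):
        result = TestResult(
            name="rm_anova",
            statistic=float(row["F"]),
            df=(float(row["DF"]), float(aov.iloc[1]["DF"])),
            p=float(row["p_unc"]),
            effect_size_name="partial_eta_sq",
            effect_size=float(row["np2"]),
        )
    else:
        # degenerate input (zero effect and zero error variance): no signal
        result = TestResult(
            name="rm_anova",
            statistic=0.0,
            df=(float(k - 1), float((n - 1) * (k - 1))),
            p=1.0,
            effect_size_name="partial_eta_sq",
            effect_size=0.0,
        )
    if posthoc:
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                t = paired_t_cohend(arr[:, i], arr[:, j])
                rows.append(
                    {"a": i, "b": j, "t": t.statistic, "p": t.p, "d": t.effect_size}
                )
        tab = pd.DataFrame(rows)
        tab["p_fdr"] = multipletests(tab["p"], method="fdr_bh")[1]
        result.extra["posthoc"] = tab
    return result
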