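"""Cohort statistics with normality gating.

Continuous variables are summarised as mean ± SD when a Shapiro–Wilk test
(α = 0.05) does not reject normality, otherwise as median (Q1, Q3); the
same gate selects Student's t vs Mann–Whitney U between groups, paired t
vs Wilcoxon signed-rank within group, and Pearson's r vs Spearman's rho
for correlations.  Bonferroni correction, ordinary-least-squares
multivariable regression with optional log-transformed predictors and
standardized betas, and a noncentral-t sample-size computation round out
the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NORMALITY_ALPHA",
    "TestResult",
    "RegressionResult",
    "is_normal",
    "summarize",
    "group_compare",
    "paired_compare",
    "bonferroni",
    "correlate",
    "multivariable_fit",
    "sample_size_two_t",
]

NORMALITY_ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # t | mann_whitney | paired_t | wilcoxon
    n_per_group: tuple[int, ...]
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class RegressionResult:
    coefficients: pd.Series
    standard_errors: pd.Series
    standardized_betas: pd.Series
    p_values: pd.Series
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "standard_error": self.standard_errors,
                "standardized_beta": self.standardized_betas,
                "p_value": self.p_values,
            }
        )


def is_normal(values, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro–Wilk normality gate; deterministic given the data.

    Degenerate (constant) samples are treated as non-normal so downstream
    choices fall back to rank-based summaries/tests.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("normality gate requires n >= 3")
    if np.ptp(x) == 0:
        return False
    return bool(sps.shapiro(x).pvalue > alpha)


def summarize(values, alpha: float = NORMALITY_ALPHA) -> dict:
    """Mean ± SD if the normality gate passes, else median (Q1, Q3)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("summarize requires n >= 3")
    normal = is_normal(x, alpha)
    if normal:
        return {
            "kind": "mean_sd",
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "n": len(x),
        }
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "kind": "median_iqr",
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": len(x),
    }


def group_compare(
    values,
    groups,
    alpha: float = NORMALITY_ALPHA,
    method: str = "auto",
) -> TestResult:
    """Two-sided two-group comparison, test chosen by the normality gate.

    With ``method="auto"`` Student's t is used when both groups pass the
    Shapiro–Wilk gate, otherwise the Mann–Whitney U test (exact when the
    combined n ≤ 20 and there are no ties, normal approximation with tie
    correction otherwise).  ``method`` may be forced to ``"t"`` or
    ``"mann_whitney"``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")

    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(
            statistic=float("nan"),
            p_value=1.0,
            method="t" if method == "t" else "mann_whitney",
            n_per_group=(len(a), len(b)),
            degenerate=True,
            notes=["all values identical across both groups"],
        )

    if method == "auto":
        method = "t" if (is_normal(a, alpha) and is_normal(b, alpha)) else "mann_whitney"

    if method == "t":
        stat, p = sps.ttest_ind(a, b)
        return TestResult(float(stat), float(p), "t", (len(a), len(b)))
    if method == "mann_whitney":
        n_tot = len(a) + len(b)
        has_ties = len(np.unique(np.concatenate([a, b]))) < n_tot
        mw_method = "exact" if (n_tot <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        return TestResult(
            float(res.statistic),
            float(res.pvalue),
            "mann_whitney",
            (len(a), len(b)),
            notes=[f"mannwhitney_method={mw_method}"],
        )
    raise ValueError(f"unknown method {method!r}")


def paired_compare(values_a, values_b, alpha: float = NORMALITY_ALPHA) -> TestResult:
    """Two-sided paired comparison on the differences.

    Paired t when the differences pass the normality gate, Wilcoxon
    signed-rank otherwise.  All-zero differences give p = 1 (degenerate);
    a constant non-zero shift has zero SD and is flagged as an exact shift
    with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("paired comparison needs n >= 3")
    d = a - b
    n = len(d)
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "paired_t", (n,), degenerate=True,
                          notes=["zero differences"])
    if np.ptp(d) == 0:
        # constant non-zero shift: paired-t statistic is singular
        return TestResult(math.inf, 0.0, "paired_t", (n,), degenerate=True,
                          notes=["exact constant shift; SD of differences is 0"])
    if is_normal(d, alpha):
        stat, p = sps.ttest_rel(a, b)
        return TestResult(float(stat), float(p), "paired_t", (n,))
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon", (n,))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p' = min(1, m·p); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m_eff * p)


def correlate(x, y, alpha: float = NORMALITY_ALPHA, method: str = "auto") -> dict:
    """Pearson's r (both variables gated normal) or Spearman's rho.

    Returns ``{"estimate", "p", "method"}`` with a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError("correlation needs n >= 5 finite pairs")
    if method == "auto":
        method = "pearson" if (is_normal(x, alpha) and is_normal(y, alpha)) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"estimate": float(r), "p": float(p), "method": method}


def multivariable_fit(
    y,
    predictors: pd.DataFrame,
    log_flags: dict[str, bool] | None = None,
    log_y: bool = False,
) -> RegressionResult:
    """OLS of y on the predictors with optional natural-log transforms.

    ``log_flags`` maps predictor names to whether they are log-transformed
    before fitting (zero/negative values are an error — no offsets).
    Standardized beta = coefficient × SD(x) / SD(y), computed on the
    transformed scales.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float).copy()
    log_flags = log_flags or {}
    for name, flag in log_flags.items():
        if not flag:
            continue
        if name not in X.columns:
            raise KeyError(f"unknown predictor {name!r}")
        if (X[name] <= 0).any():
            raise ValueError(f"cannot log-transform non-positive values in {name!r}")
        X[name] = np.log(X[name])
    if log_y:
        if (y <= 0).any():
            raise ValueError("cannot log-transform non-positive response values")
        y = np.log(y)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        cols: list[str] = []
        for c in design.columns:
            cols.append(c)
            sub = design[cols].to_numpy()
            if np.linalg.matrix_rank(sub) < len(cols):
                bad.append(c)
                cols.pop()
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    sd_y = float(np.std(y, ddof=1))
    betas = {}
    for c in X.columns:
        betas[c] = float(fit.params[c] * np.std(X[c], ddof=1) / sd_y)
    keep = list(X.columns)
    return RegressionResult(
        coefficients=fit.params[keep],
        standard_errors=fit.bse[keep],
        standardized_betas=pd.Series(betas)[keep],
        p_values=fit.pvalues[keep],
        r_squared=float(fit.rsquared),
        n=n,
    )


def _two_t_power(n: int, d: float, alpha: float) -> float:
    """Power of a two-sided two-sample t test at n per group, effect d."""
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_t(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    power: float = 0.8,
    alpha: float = 0.05,
    max_n: int = 10_000,
) -> int:
    """Smallest n per group for a two-sided two-sample t test.

    Cohen's d uses the pooled SD, sqrt((sd1² + sd2²)/2) (equal allocation);
    power is the exact noncentral-t power function.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    d = abs(mean1 - mean2) / pooled
    if d == 0:
        raise ValueError("zero effect: no finite sample size achieves power")
    for n in range(2, max_n + 1):
        if _two_t_power(n, d, alpha) >= power:
            return n
    raise ValueError(f"no n <= {max_n} achieves the requested power")
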