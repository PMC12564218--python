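"""Statistical battery: correlation method selection, confidence
intervals, quartile group comparisons, and the a-priori sample size.

Method selection mirrors common clinical-statistics practice: Pearson's r
is used only when both variables pass the Shapiro-Wilk normality test and
show no outliers (beyond 3 scaled-MAD from the median); otherwise the
rank-based Spearman coefficient is used. Confidence intervals use the
Fisher z-transform, with the standard 1.06/(n-3) variance inflation for
Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConstantInputError, UndefinedCorrelationError


@dataclass(frozen=True)
class CorrelationResult:
    """One index/score correlation with Fisher-z confidence interval."""

    index_name: str
    score_name: str
    method: str          # "pearson" | "spearman"
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class GroupComparison:
    """Lowest-quartile versus remainder comparison for one variable."""

    variable: str
    test_used: str       # t_test | mann_whitney | chi_square | fisher_exact | degenerate
    low_mean: float
    low_sd: float
    rest_mean: float
    rest_sd: float
    p_value: float
    n_low: int
    n_rest: int


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def normality_p(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value; p <= 0.05 flags a non-normal distribution."""
    x = np.asarray(values, float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {len(x)}")
    if np.ptp(x) == 0.0:
        raise ConstantInputError("normality test undefined on constant input")
    return float(sps.shapiro(x).pvalue)


def _has_outlier(x: np.ndarray) -> bool:
    """Outlier rule: any |value - median| > 3 * scaled MAD."""
    mad = sps.median_abs_deviation(x, scale="normal")
    if mad == 0.0:
        return bool(np.ptp(x) > 0)
    return bool(np.any(np.abs(x - np.median(x)) > 3.0 * mad))


def choose_method(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> str:
    """Pearson when both variables are normal and outlier-free, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise ValueError("method selection needs n >= 4")
    try:
        normal = normality_p(x) > alpha and normality_p(y) > alpha
    except ConstantInputError:
        return "spearman"
    if not normal or _has_outlier(x) or _has_outlier(y):
        return "spearman"
    return "pearson"


#: Fisher-z variance inflation for Spearman's rho (Fieller-style correction)
_SPEARMAN_VAR_INFLATION = 1.06


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str,
    index_name: str = "x",
    score_name: str = "y",
    conf: float = 0.95,
) -> CorrelationResult:
    """Correlation coefficient with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 4:
        raise ValueError("correlation CI needs n >= 4")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    if method == "pearson":
        res = sps.pearsonr(x, y)
        se = 1.0 / np.sqrt(n - 3)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
        se = np.sqrt(_SPEARMAN_VAR_INFLATION / (n - 3))
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(res.statistic)
    p = float(res.pvalue)
    zc = sps.norm.ppf(0.5 + conf / 2.0)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(index_name, score_name, method, r,
                             float(lo), float(hi), p, n)


# --------------------------------------------------------------------------
# report batteries

#: (index column in the wide AoC table) per subset, battery row order
_BATTERY_SUBSETS = ("S4", "S5", "S6", "S9", "DCT")


def correlation_battery(
    aoc_wide: pd.DataFrame,
    qol: pd.DataFrame,
    va40: Optional[pd.Series] = None,
    va300: Optional[pd.Series] = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """The full index-versus-score correlation report.

    Pairs the total AoC of each subset with the total score, near AoC
    (plus single VA at 40 cm) with the near-activities score, and distance
    AoC (plus single VA at 300 cm) with the distance-activities score —
    17 rows for the full battery. The method for each pair is chosen by
    :func:`choose_method`. ``aoc_wide`` must be indexed by patient id
    (see :func:`vicurve.curves.aoc_wide`); ``qol`` must carry patient_id
    and the three score columns. Optionally applies a Holm adjustment to
    the p-values (off by default).
    """
    q = qol.set_index("patient_id").loc[aoc_wide.index]
    present = [s for s in _BATTERY_SUBSETS if f"total_{s}" in aoc_wide.columns]
    pairs: List[Tuple[str, pd.Series, str]] = []
    for sub in present:
        pairs.append((f"total_{sub}", aoc_wide[f"total_{sub}"], "total_score"))
    for sub in present:
        pairs.append((f"near_{sub}", aoc_wide[f"near_{sub}"], "near_activities"))
    if va40 is not None:
        pairs.append(("va_40cm", va40.loc[aoc_wide.index], "near_activities"))
    for sub in present:
        pairs.append((f"distance_{sub}", aoc_wide[f"distance_{sub}"], "distance_activities"))
    if va300 is not None:
        pairs.append(("va_300cm", va300.loc[aoc_wide.index], "distance_activities"))

    rows = []
    for index_name, series, score_name in pairs:
        x = np.asarray(series, float)
        y = np.asarray(q[score_name], float)
        method = choose_method(x, y, alpha=alpha)
        res = correlate(x, y, method, index_name, score_name)
        rows.append((res.index_name, res.score_name, res.method, res.r,
                     res.ci_low, res.ci_high, res.p_value, res.n, res.stars))
    out = pd.DataFrame(rows, columns=[
        "index_name", "score_name", "method", "r",
        "ci_low", "ci_high", "p_value", "n", "stars",
    ])
    if holm:
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1]
        out["stars"] = [significance_stars(p) for p in out["p_adjusted"]]
    return out


def normality_table(variables: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """Shapiro-Wilk p per named variable (the normality report)."""
    rows = []
    for name, vals in variables.items():
        try:
            p = normality_p(vals)
        except (ConstantInputError, ValueError):
            p = np.nan
        rows.append((name, p, "non-normal" if (np.isfinite(p) and p <= 0.05) else
                     ("normal" if np.isfinite(p) else "undefined")))
    return pd.DataFrame(rows, columns=["variable", "shapiro_p", "assessment"])


def quartile_compare(
    variables: pd.DataFrame,
    scores: pd.Series,
    alpha: float = 0.05,
) -> List[GroupComparison]:
    """Compare each variable between the lowest score quartile and the rest.

    The lowest group is everyone at or below the 25th percentile of the
    chosen score. Continuous variables use Student's t-test when both
    groups pass normality, otherwise Mann-Whitney U; categorical variables
    use the chi-square test, or Fisher's exact test when any expected cell
    count falls below 5 (2x2 tables).
    """
    scores = scores.loc[variables.index]
    n = len(scores)
    if n < 8:
        raise ValueError(f"quartile comparison needs n >= 8, got {n}")
    q25 = float(scores.quantile(0.25))
    low_mask = scores <= q25
    n_low, n_rest = int(low_mask.sum()), int((~low_mask).sum())
    if min(n_low, n_rest) < 3:
        raise ValueError(
            f"quartile split produced a group below 3 members ({n_low} vs {n_rest})"
        )

    results: List[GroupComparison] = []
    for col in variables.columns:
        v = variables[col]
        if pd.api.types.is_numeric_dtype(v):
            a = np.asarray(v[low_mask], float)
            b = np.asarray(v[~low_mask], float)
            if np.ptp(np.concatenate([a, b])) == 0.0:
                results.append(GroupComparison(
                    col, "degenerate", float(a.mean()), 0.0,
                    float(b.mean()), 0.0, 1.0, n_low, n_rest))
                continue
            try:
                normal = normality_p(a) > alpha and normality_p(b) > alpha
            except (ConstantInputError, ValueError):
                normal = False
            if normal:
                test, p = "t_test", float(sps.ttest_ind(a, b, equal_var=True).pvalue)
            else:
                test, p = "mann_whitney", float(
                    sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            results.append(GroupComparison(
                col, test, float(a.mean()), float(a.std(ddof=1)),
                float(b.mean()), float(b.std(ddof=1)), p, n_low, n_rest))
        else:
            table = pd.crosstab(low_mask, v)
            if table.shape[1] < 2:
                results.append(GroupComparison(
                    col, "degenerate", np.nan, np.nan, np.nan, np.nan,
                    1.0, n_low, n_rest))
                continue
            chi2 = sps.chi2_contingency(table.values)
            if (chi2.expected_freq < 5).any() and table.shape == (2, 2):
                test = "fisher_exact"
                p = float(sps.fisher_exact(table.values).pvalue)
            else:
                test = "chi_square"
                p = float(chi2.pvalue)
            results.append(GroupComparison(
                col, test, np.nan, np.nan, np.nan, np.nan, p, n_low, n_rest))
    return results


def comparisons_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    rows = [(c.variable, c.test_used, c.low_mean, c.low_sd, c.rest_mean,
             c.rest_sd, c.p_value, significance_stars(c.p_value),
             c.n_low, c.n_rest) for c in comparisons]
    return pd.DataFrame(rows, columns=[
        "variable", "test_used", "lowest_quartile_mean", "lowest_quartile_sd",
        "remainder_mean", "remainder_sd", "p_value", "stars", "n_low", "n_rest",
    ])


def required_n(r: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2) -> int:
    """Minimum sample size to detect correlation r (Fisher-z approximation).

    n = ceil(((z_{1-alpha/tails} + z_{power}) / atanh(r))^2 + 3), floored
    at the minimum of 4 observations needed for a correlation CI.
    """
    if not (0.0 < abs(r) < 1.0):
        raise ValueError("expected effect size r must satisfy 0 < |r| < 1")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    za = sps.norm.ppf(1.0 - alpha / tails)
    zb = sps.norm.ppf(power)
    n = int(np.ceil(((za + zb) / np.arctanh(abs(r))) ** 2 + 3.0))
    return max(n, 4)
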