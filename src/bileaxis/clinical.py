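"""Clinical covariate statistics and AF association modelling.

Implements the baseline-characteristics comparison (t test or
Mann-Whitney for continuous variables gated by a Shapiro-Wilk normality
check; chi-square with Yates continuity or Fisher exact for categorical),
the FGF19-LAD Pearson correlation, and the two-stage logistic workflow:
a univariate screen at p < 0.10 with forced-in covariates, then a
multivariable maximum-likelihood fit with Wald intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .profiling import wilcoxon_rank_sum
from .simulate import AF_LABEL, CONTROL_LABEL

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


def t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sided pooled-variance Student t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y):
    """Pearson r with two-sided t p-value over complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _normalish(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > 0.05


def baseline_table(
    table: pd.DataFrame,
    group_col: str = "group",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable AF vs control comparison in the Table-1 convention.

    Continuous variables use the pooled Student t when both groups pass
    Shapiro-Wilk (p > 0.05), otherwise Mann-Whitney; binary variables use
    chi-square with Yates continuity, falling back to Fisher exact when any
    expected cell count is below 5.
    """
    groups = table[group_col]
    af = table[groups == AF_LABEL]
    ctl = table[groups == CONTROL_LABEL]
    if len(af) < 2 or len(ctl) < 2:
        raise ValueError("need at least 2 subjects per group")
    if variables is None:
        variables = [c for c in table.columns if c != group_col]
    rows = []
    for var in variables:
        a = af[var].dropna()
        c = ctl[var].dropna()
        if a.empty and c.empty:
            warnings.warn(f"variable {var!r} is all-missing; skipped")
            continue
        if _is_binary(table[var]):
            counts = np.array([
                [int(a.sum()), int(len(a) - a.sum())],
                [int(c.sum()), int(len(c) - c.sum())],
            ])
            expected = stats.contingency.expected_freq(counts) \
                if counts.sum() else np.zeros((2, 2))
            if (expected < 5).any():
                stat, p = np.nan, stats.fisher_exact(counts)[1]
                test = "fisher"
            else:
                chi2 = stats.chi2_contingency(counts, correction=True)
                stat, p, test = chi2.statistic, chi2.pvalue, "chi-square"
            summary_af = f"{counts[0, 0]} ({100 * counts[0, 0] / len(a):.2f}%)"
            summary_ctl = f"{counts[1, 0]} ({100 * counts[1, 0] / len(c):.2f}%)"
        else:
            a_np, c_np = a.to_numpy(float), c.to_numpy(float)
            if _normalish(a_np) and _normalish(c_np):
                stat, p = t_test_from_summary(
                    a_np.mean(), a_np.std(ddof=1), len(a_np),
                    c_np.mean(), c_np.std(ddof=1), len(c_np))
                test = "t"
                summary_af = f"{a_np.mean():.2f} ± {a_np.std(ddof=1):.2f}"
                summary_ctl = f"{c_np.mean():.2f} ± {c_np.std(ddof=1):.2f}"
            else:
                stat, p = np.nan, wilcoxon_rank_sum(a_np, c_np)
                test = "mann-whitney"
                qa = np.percentile(a_np, [25, 50, 75])
                qc = np.percentile(c_np, [25, 50, 75])
                summary_af = f"{qa[1]:.2f} ({qa[0]:.2f}-{qa[2]:.2f})"
                summary_ctl = f"{qc[1]:.2f} ({qc[0]:.2f}-{qc[2]:.2f})"
        rows.append({
            "variable": var, "summary_AF": summary_af,
            "summary_control": summary_ctl, "test": test,
            "statistic": float(stat) if np.isfinite(stat) else np.nan,
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals."""

    variables: list[str]
    coef: pd.Series
    se: pd.Series
    odds_ratio: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    converged: bool

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "OR": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_values,
        })


def fit_logistic(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
) -> LogisticModel:
    """Multivariable logistic regression of AF (=1) on the given variables.

    Complete-case analysis; Newton (IRLS-equivalent) maximum likelihood
    with a 1e-8 tolerance.  Perfect separation is reported through the
    ``converged`` flag rather than silently returned.
    """
    cols = [group_col] + list(variables)
    data = table[cols].dropna()
    y = (data[group_col] == AF_LABEL).astype(float)
    x = sm.add_constant(data[list(variables)].astype(float), has_constant="add")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, method="newton", tol=1e-8)
        converged = bool(fit.mle_retvals.get("converged", False))
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise RuntimeError(f"logistic fit failed (separation?): {err}") from None
    coef, se = fit.params, fit.bse
    return LogisticModel(
        variables=list(variables),
        coef=coef,
        se=se,
        odds_ratio=np.exp(coef),
        ci_low=np.exp(coef - Z95 * se),
        ci_high=np.exp(coef + Z95 * se),
        p_values=fit.pvalues,
        converged=converged,
    )


def univariate_screen(
    table: pd.DataFrame,
    alpha: float = 0.100,
    forced: tuple[str, ...] = ("DM",),
    group_col: str = "group",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """One single-predictor logistic fit per variable.

    Returns OR, Wald CI and p per variable with a ``selected`` flag:
    p < alpha, union the forced-in set.  Variables hitting separation are
    flagged (``converged`` False) and kept with a logged warning.
    """
    if variables is None:
        variables = [c for c in table.columns if c != group_col]
    rows = []
    for var in variables:
        try:
            model = fit_logistic(table, [var], group_col=group_col)
            or_, lo, hi = (model.odds_ratio[var], model.ci_low[var],
                           model.ci_high[var])
            p = model.p_values[var]
            converged = model.converged
        except RuntimeError as err:
            logger.warning("univariate fit for %s: %s", var, err)
            or_ = lo = hi = p = np.nan
            converged = False
        if not converged:
            logger.warning("separation/non-convergence for %s; retained", var)
        rows.append({
            "variable": var, "OR": float(or_), "ci_low": float(lo),
            "ci_high": float(hi), "p_value": float(p),
            "converged": converged,
            "selected": bool(var in forced or (np.isfinite(p) and p < alpha)),
        })
    return pd.DataFrame(rows)
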