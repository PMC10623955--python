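"""Receiver-operating-characteristic analysis for single biomarkers.

The AUC is the normalised Mann-Whitney U statistic (ties count one half),
its 95% confidence interval comes from DeLong's asymptotic variance of the
placement values, and the operating cutpoint maximises the Youden index
J = sensitivity + specificity - 1, reported as the midpoint between the
adjacent observed marker values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RocCurve:
    """Empirical ROC curve of one marker.

    ``orientation`` is ">" when higher marker values indicate a case and
    "<" when the curve had to be flipped so that AUC >= 0.5.  Thresholds,
    the cutpoint and the sensitivities/specificities are always reported on
    the original marker scale.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    optimal_cutpoint: float
    sens_at_cut: float
    spec_at_cut: float
    orientation: str


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC = U / (n1 n0) with tied pairs counted one half."""
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    m = len(cases)
    r1 = ranks[:m].sum()
    u = r1 - m * (m + 1) / 2.0
    return float(u / (m * len(controls)))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via midrank placements."""
    m, n = len(cases), len(controls)
    pooled = np.concatenate([cases, controls])
    rank_all = stats.rankdata(pooled)
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    # placement of each case among controls and vice versa
    v10 = (rank_all[:m] - rank_cases) / n
    v01 = 1.0 - (rank_all[m:] - rank_controls) / m
    if m < 2 or n < 2:
        return float("nan")
    s10 = np.var(v10, ddof=1)
    s01 = np.var(v01, ddof=1)
    return float(s10 / m + s01 / n)


def roc_analysis(
    values,
    labels,
    direction: str = "auto",
    positive_label=None,
) -> RocCurve:
    """Evaluate one marker against a binary outcome.

    Parameters
    ----------
    values : marker measurements
    labels : boolean/0-1 case indicators, or arbitrary labels with
        ``positive_label`` naming the case class
    direction : ">", "<" or "auto"; auto flips the marker so AUC >= 0.5
        and records which way it ended up
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if positive_label is not None:
        case_mask = labels == positive_label
    else:
        case_mask = labels.astype(bool)
    cases = values[case_mask]
    controls = values[~case_mask]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")

    if direction == "auto":
        direction = ">" if _auc_mann_whitney(cases, controls) >= 0.5 else "<"
    elif direction not in (">", "<"):
        raise ValueError("direction must be '>', '<' or 'auto'")
    sign = 1.0 if direction == ">" else -1.0
    c, k = sign * cases, sign * controls

    auc = _auc_mann_whitney(c, k)
    var = _delong_variance(c, k)
    half = 1.959963984540054 * np.sqrt(var) if np.isfinite(var) else 0.0
    ci = (float(np.clip(auc - half, 0.0, 1.0)),
          float(np.clip(auc + half, 0.0, 1.0)))

    # candidate cutpoints: midpoints between adjacent observed values
    uniq = np.unique(np.concatenate([c, k]))
    if len(uniq) > 1:
        cuts = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        cuts = np.array([uniq[0]])
    sens = np.array([(c > cut).mean() for cut in cuts])
    spec = np.array([(k <= cut).mean() for cut in cuts])
    j = sens + spec - 1.0
    # smallest cutpoint among maximal-J candidates, on the original scale
    best = np.flatnonzero(j >= j.max() - 1e-12)
    original_cuts = sign * cuts
    idx = best[np.argmin(original_cuts[best])]

    return RocCurve(
        thresholds=original_cuts,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci95=ci,
        optimal_cutpoint=float(original_cuts[idx]),
        sens_at_cut=float(sens[idx]),
        spec_at_cut=float(spec[idx]),
        orientation=direction,
    )
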