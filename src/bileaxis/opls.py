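"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

A NIPALS fit with orthogonal-signal correction: variation in X orthogonal
to the class vector y is estimated component by component and deflated
before a single predictive component is extracted.  Variable importance in
projection (VIP) is computed on the predictive component, so that the mean
of the squared VIPs over variables is exactly 1 and VIP > 1 marks
above-average contributors.  Predictive power is summarised by Q2 from
k-fold "venetian blind" cross-validation (interleaved sample folds).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AF_LABEL

logger = logging.getLogger(__name__)


@dataclass
class ScalingParams:
    """log10 + unit-variance scaling parameters, fit on training data."""

    variables: list[str]
    eps: np.ndarray      # half-minimum-nonzero pseudo-count per variable
    mean: np.ndarray
    sd: np.ndarray
    log_transform: bool

    def apply(self, panel: pd.DataFrame) -> np.ndarray:
        x = panel[self.variables].to_numpy(dtype=float)
        if self.log_transform:
            x = np.log10(x + self.eps[None, :])
        return (x - self.mean[None, :]) / self.sd[None, :]


def fit_scaling(
    panel: pd.DataFrame, log_transform: bool = True
) -> ScalingParams:
    """Fit the default metabolomics scaling: log10(x + eps), centre, unit SD.

    eps is half the smallest nonzero value per variable (0 for all-zero
    columns).  Variables that end up constant are dropped with a warning.
    """
    x = panel.to_numpy(dtype=float)
    if log_transform and (x < 0).any():
        raise ValueError("negative concentrations cannot be log-scaled")
    eps = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        nz = x[:, j][x[:, j] > 0]
        eps[j] = nz.min() / 2.0 if nz.size else 0.0
    xt = np.log10(x + eps[None, :]) if log_transform else x.copy()
    sd = xt.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(panel.columns[~keep])
        warnings.warn(f"dropping constant variables: {dropped}")
    variables = list(panel.columns[keep])
    return ScalingParams(
        variables=variables,
        eps=eps[keep],
        mean=xt[:, keep].mean(axis=0),
        sd=sd[keep],
        log_transform=log_transform,
    )


@dataclass
class OplsDaModel:
    """A fitted OPLS-DA model with one predictive component.

    ``weights`` (unit norm), ``loadings`` and ``vip`` are indexed by
    variable; ``scores`` holds the predictive scores t and
    ``orthogonal_scores`` one column per orthogonal component.
    """

    variables: list[str]
    weights: pd.Series
    loadings: pd.Series
    scores: np.ndarray
    orthogonal_scores: np.ndarray
    orthogonal_weights: np.ndarray
    orthogonal_loadings: np.ndarray
    q: float
    y_mean: float
    vip: pd.Series
    r2x: float
    r2y: float
    q2: float | None
    scaling: ScalingParams

    def predict_score(self, panel: pd.DataFrame) -> np.ndarray:
        """Predictive score of new samples after orthogonal filtering."""
        x = self.scaling.apply(panel)
        for a in range(self.orthogonal_weights.shape[1]):
            t_o = x @ self.orthogonal_weights[:, a]
            x = x - np.outer(t_o, self.orthogonal_loadings[:, a])
        return x @ self.weights.to_numpy()

    def predict_y(self, panel: pd.DataFrame) -> np.ndarray:
        return self.predict_score(panel) * self.q + self.y_mean


def _opls_core(x: np.ndarray, yc: np.ndarray, n_orthogonal: int):
    """NIPALS orthogonal-signal-correction fit on already-scaled data."""
    n, k = x.shape
    w_orth = np.zeros((k, n_orthogonal))
    p_orth = np.zeros((k, n_orthogonal))
    t_orth = np.zeros((n, n_orthogonal))
    xr = x.copy()
    for a in range(n_orthogonal):
        w = xr.T @ yc
        w /= np.linalg.norm(w)
        t = xr @ w
        p = xr.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            # no orthogonal variation left; keep a zero component
            break
        wo /= norm
        to = xr @ wo
        po = xr.T @ to / (to @ to)
        xr = xr - np.outer(to, po)
        w_orth[:, a], p_orth[:, a], t_orth[:, a] = wo, po, to
    w = xr.T @ yc
    w /= np.linalg.norm(w)
    t = xr @ w
    p = xr.T @ t / (t @ t)
    q = float((yc @ t) / (t @ t))
    return w, t, p, q, w_orth, p_orth, t_orth, xr


def _encode_y(groups: pd.Series, index) -> np.ndarray:
    y = (groups.reindex(index).to_numpy() == AF_LABEL).astype(float)
    return y


def fit_oplsda(
    panel: pd.DataFrame,
    groups: pd.Series,
    n_orthogonal: int = 1,
    log_transform: bool = True,
    q2_folds: int = 7,
    compute_q2: bool = True,
) -> OplsDaModel:
    """Fit OPLS-DA of the sample x variable table against AF vs control.

    y is coded AF = 1 / control = 0 and centred; X is log10 + unit-variance
    scaled.  ``n_orthogonal`` components are deflated before the single
    predictive component.  Q2 uses ``q2_folds`` interleaved folds with the
    scaling refit inside each training fold.
    """
    y = _encode_y(groups, panel.index)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 samples per group")
    scaling = fit_scaling(panel, log_transform=log_transform)
    x = scaling.apply(panel)
    rank = np.linalg.matrix_rank(x)
    if n_orthogonal < 0 or n_orthogonal >= rank:
        raise ValueError(
            f"n_orthogonal must be in [0, rank={rank}) for this matrix")
    y_mean = float(y.mean())
    yc = y - y_mean

    w, t, p, q, w_orth, p_orth, t_orth, xr = _opls_core(x, yc, n_orthogonal)

    k = len(scaling.variables)
    vip = np.sqrt(k) * np.abs(w)  # single predictive component
    ssx = (x ** 2).sum()
    explained = (t @ t) * (p @ p)
    for a in range(t_orth.shape[1]):
        explained += (t_orth[:, a] @ t_orth[:, a]) * (p_orth[:, a] @ p_orth[:, a])
    r2x = float(explained / ssx)
    resid = yc - t * q
    r2y = float(1.0 - (resid @ resid) / (yc @ yc))

    q2 = None
    if compute_q2:
        q2 = _venetian_blind_q2(
            panel, y, n_orthogonal, log_transform, q2_folds)

    return OplsDaModel(
        variables=list(scaling.variables),
        weights=pd.Series(w, index=scaling.variables, name="w"),
        loadings=pd.Series(p, index=scaling.variables, name="p"),
        scores=t,
        orthogonal_scores=t_orth,
        orthogonal_weights=w_orth,
        orthogonal_loadings=p_orth,
        q=q,
        y_mean=y_mean,
        vip=pd.Series(vip, index=scaling.variables, name="VIP"),
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        scaling=scaling,
    )


def _venetian_blind_q2(panel, y, n_orthogonal, log_transform, folds):
    n = len(panel)
    folds = min(folds, n)
    press = 0.0
    for f in range(folds):
        test = np.arange(n) % folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        scaling = fit_scaling(panel.iloc[train], log_transform=log_transform)
        x_tr = scaling.apply(panel.iloc[train])
        y_mean = y[train].mean()
        yc = y[train] - y_mean
        n_o = min(n_orthogonal, max(np.linalg.matrix_rank(x_tr) - 1, 0))
        w, t, p, q, w_orth, p_orth, _, _ = _opls_core(x_tr, yc, n_o)
        x_te = scaling.apply(panel.iloc[test])
        for a in range(w_orth.shape[1]):
            t_o = x_te @ w_orth[:, a]
            x_te = x_te - np.outer(t_o, p_orth[:, a])
        yhat = (x_te @ w) * q + y_mean
        press += float(((y[test] - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def vip_select(
    model: OplsDaModel,
    threshold: float = 1.0,
    p_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Variables with VIP strictly above the threshold.

    VIP_j = sqrt(K * sum_a w_ja^2 SSY_a / sum_a SSY_a) over the predictive
    component(s); with one predictive component this is sqrt(K)|w_j|.  If a
    differential-test table is given (columns feature / p_value), each
    selected variable is annotated with its Wilcoxon p.
    """
    out = pd.DataFrame({
        "variable": model.vip.index,
        "vip": model.vip.to_numpy(),
    })
    if p_table is not None:
        pmap = dict(zip(p_table["feature"], p_table["p_value"]))
        out["p_value"] = [pmap.get(v, np.nan) for v in out["variable"]]
    out = out[out["vip"] > threshold]
    return out.sort_values("vip", ascending=False).reset_index(drop=True)
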