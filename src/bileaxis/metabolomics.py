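"""Faecal bile-acid panel analysis: composition, differential BAs, PCA.

The targeted panel reports absolute concentrations (nmol/g dry faeces) for
24 bile acids.  Composition summaries split the pool into host-derived
primary BAs and microbially derived secondary BAs; group comparisons use
the Wilcoxon rank-sum test shared with the metagenomic stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .vocab import BA_CLASS_MAP
from .profiling import differential_features, wilcoxon_rank_sum
from .simulate import AF_LABEL, CONTROL_LABEL
from .opls import fit_scaling


@dataclass
class CompositionSummary:
    """Per-sample totals and the secondary-proportion group comparison."""

    per_sample: pd.DataFrame      # total, secondary_total, secondary_prop
    p_value: float                # Wilcoxon on secondary proportion
    median_prop_af: float
    median_prop_control: float
    excluded_samples: list[str]   # zero-total samples, flagged out


def summarize_composition(
    panel: pd.DataFrame,
    groups: pd.Series,
    class_map: Mapping[str, Mapping[str, str]] | None = None,
) -> CompositionSummary:
    """Total BA pool and the secondary-BA proportion, compared AF vs control.

    Samples with a zero total have no defined proportion; they are flagged
    in ``excluded_samples`` and left out of the group test.
    """
    cmap = class_map or BA_CLASS_MAP
    missing = set(panel.columns) - set(cmap)
    if missing:
        raise ValueError(f"class map does not cover: {sorted(missing)}")
    secondary_cols = [c for c in panel.columns if cmap[c]["class"] == "secondary"]
    total = panel.sum(axis=1)
    secondary = panel[secondary_cols].sum(axis=1)
    prop = secondary.where(total > 0) / total.where(total > 0)
    per_sample = pd.DataFrame({
        "total": total,
        "secondary_total": secondary,
        "secondary_prop": prop,
        "group": groups.reindex(panel.index),
    })
    excluded = list(per_sample.index[total <= 0])
    valid = per_sample.dropna(subset=["secondary_prop"])
    af = valid.loc[valid["group"] == AF_LABEL, "secondary_prop"].to_numpy()
    ctl = valid.loc[valid["group"] == CONTROL_LABEL, "secondary_prop"].to_numpy()
    return CompositionSummary(
        per_sample=per_sample,
        p_value=wilcoxon_rank_sum(af, ctl),
        median_prop_af=float(np.median(af)),
        median_prop_control=float(np.median(ctl)),
        excluded_samples=excluded,
    )


def differential_bas(panel: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-BA Wilcoxon comparison plus volcano-plot coordinates.

    Returns the differential-feature table with two extra columns:
    ``volcano_x`` (log2 median fold change, AF over control) and
    ``volcano_y`` (-log10 p).
    """
    result = differential_features(panel.T, groups)
    result["volcano_x"] = result["log2_fc"]
    with np.errstate(divide="ignore"):
        result["volcano_y"] = -np.log10(result["p_value"])
    return result


@dataclass
class PcaResult:
    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # variables x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scaling_variables: list[str]


def pca_scores(
    panel: pd.DataFrame,
    log_transform: bool = True,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of the scaled panel (log10 + unit variance, as for OPLS-DA).

    Constant variables are dropped by the scaler with a warning.  With all
    components kept, scores @ loadings.T reproduces the scaled matrix to
    numerical precision.
    """
    if panel.shape[0] < 2 or panel.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    from sklearn.decomposition import PCA

    scaling = fit_scaling(panel, log_transform=log_transform)
    x = scaling.apply(panel)
    max_rank = min(x.shape)
    pca = PCA(n_components=n_components or max_rank, svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=panel.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=scaling.variables, columns=comp_names),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scaling_variables=list(scaling.variables),
    )
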