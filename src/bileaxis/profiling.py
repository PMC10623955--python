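"""Gene-level functional profiling of bile-acid enzymes.

Alignment hits of catalogue genes against the 13 BA-enzyme references are
filtered with the MEGAN-style 10x e-value rule, reduced to one enzyme per
gene by best hit, and summed into an enzyme x sample relative-abundance
profile.  Per-gene taxonomy hits pass through the same filter and a
lowest-common-ancestor (taxonomic LCA) step over a fixed rank ladder.
Group differences are tested feature-wise with the two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import RANKS
from .simulate import AF_LABEL, CONTROL_LABEL

#: e-values of exactly 0 are clamped here before the 10x multiplication so
#: the retention window stays meaningful.
EVALUE_FLOOR = 1e-308


def filter_significant_hits(
    hits: pd.DataFrame,
    factor: float = 10.0,
    gene_col: str = "gene_id",
    evalue_col: str = "evalue",
) -> pd.DataFrame:
    """Retain, per gene, hits with e-value <= factor x best e-value.

    The comparison is inclusive, so the top hit is always retained.  An
    empty table passes through unchanged.  Idempotent: filtering a filtered
    table is a no-op.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if hits.empty:
        return hits.copy()
    ev = hits[evalue_col].clip(lower=EVALUE_FLOOR)
    threshold = ev.groupby(hits[gene_col]).transform("min") * factor
    return hits.loc[ev <= threshold].copy()


def assign_enzyme(hits: pd.DataFrame) -> dict[str, str]:
    """Map each gene to the enzyme of its best hit.

    Best = lowest e-value, ties broken by higher bitscore, then by
    lexicographic enzyme name so the result is deterministic.  Genes with
    no hits are absent from the map.
    """
    if hits.empty:
        return {}
    ordered = hits.sort_values(
        ["gene_id", "evalue", "bitscore", "enzyme"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ordered.drop_duplicates("gene_id", keep="first")
    return dict(zip(best["gene_id"], best["enzyme"]))


def compute_enzyme_profile(
    assignments: Mapping[str, str],
    abundance: pd.DataFrame,
    enzymes: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Sum gene relative abundances per assigned enzyme.

    Parameters
    ----------
    assignments : gene_id -> enzyme name (already best-hit reduced)
    abundance : genes x samples relative abundances
    enzymes : row order of the output; defaults to the enzymes seen in the
        assignments.  Enzymes with no assigned genes get all-zero rows.
    """
    missing = [g for g in assignments if g not in abundance.index]
    if missing:
        raise KeyError(
            f"assigned genes missing from the abundance table: {missing[:5]}")
    if enzymes is None:
        enzymes = sorted(set(assignments.values()))
    profile = pd.DataFrame(
        0.0, index=list(enzymes), columns=abundance.columns)
    if assignments:
        genes = list(assignments)
        grouped = abundance.loc[genes].groupby(
            pd.Series([assignments[g] for g in genes], index=genes)).sum()
        profile.loc[grouped.index.intersection(profile.index)] = grouped
    return profile


def _validate_lineage(row: tuple) -> tuple:
    """Enforce the prefix property: no rank present below a missing rank."""
    seen_missing = False
    for value in row:
        if value == "" or pd.isna(value):
            seen_missing = True
        elif seen_missing:
            raise ValueError(f"malformed lineage (gap above a named rank): {row}")
    return tuple("" if pd.isna(v) else v for v in row)


def lca_assign(
    taxhits: pd.DataFrame,
    factor: float = 10.0,
) -> dict[str, tuple[str, ...]]:
    """Taxonomic lowest-common-ancestor assignment per gene.

    Hits are first filtered with the 10x e-value rule; the assignment is
    the deepest rank prefix shared by every retained lineage.  Genes whose
    retained hits disagree already at superkingdom map to the empty tuple
    (root / unassigned).
    """
    retained = filter_significant_hits(taxhits, factor=factor)
    out: dict[str, tuple[str, ...]] = {}
    rank_cols = list(RANKS)
    for gene, block in retained.groupby("gene_id", sort=False):
        lineages = [
            _validate_lineage(row)
            for row in block[rank_cols].itertuples(index=False, name=None)
        ]
        prefix = list(lineages[0])
        for lin in lineages[1:]:
            depth = 0
            for a, b in zip(prefix, lin):
                if a != b or a == "":
                    break
                depth += 1
            prefix = prefix[:depth]
            if not prefix:
                break
        out[str(gene)] = tuple(p for p in prefix if p != "")
    return out


def genus_of(lineage: tuple[str, ...]) -> str | None:
    """Genus of an assigned lineage, or None if it resolves above genus."""
    from .vocab import GENUS_RANK_INDEX

    if len(lineage) > GENUS_RANK_INDEX:
        return lineage[GENUS_RANK_INDEX]
    return None


# --- group testing -----------------------------------------------------------

def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups have <= 12 observations and the pooled data has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Degenerate all-equal data returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 12 and len(y) <= 12 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True).pvalue)


def _log2_fold_change(af: np.ndarray, ctl: np.ndarray) -> float:
    """log2 of the AF/control median ratio with a half-minimum pseudo-count."""
    values = np.concatenate([af, ctl])
    nonzero = values[values > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 0.0
    med_af, med_ctl = np.median(af), np.median(ctl)
    if med_af + eps <= 0 or med_ctl + eps <= 0:
        return 0.0
    return float(np.log2((med_af + eps) / (med_ctl + eps)))


def differential_features(
    table: pd.DataFrame,
    groups: pd.Series,
    add_q_values: bool = False,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum comparison of AF vs control.

    Parameters
    ----------
    table : features x samples (columns must be labelled in ``groups``)
    groups : sample -> "AF" | "control"
    add_q_values : append a Benjamini-Hochberg column (off by default; raw
        p-values are the primary output)

    Returns a frame with feature, median_AF, median_control, log2_fc,
    p_value and direction ("up" = higher in AF, ties = "none").
    """
    groups = groups.reindex(table.columns)
    af_cols = groups[groups == AF_LABEL].index
    ctl_cols = groups[groups == CONTROL_LABEL].index
    if len(af_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for feature, values in table.iterrows():
        af = values[af_cols].to_numpy(dtype=float)
        ctl = values[ctl_cols].to_numpy(dtype=float)
        med_af, med_ctl = float(np.median(af)), float(np.median(ctl))
        p = wilcoxon_rank_sum(af, ctl)
        if med_af > med_ctl:
            direction = "up"
        elif med_af < med_ctl:
            direction = "down"
        else:
            direction = "none"
        rows.append({
            "feature": feature,
            "median_AF": med_af,
            "median_control": med_ctl,
            "log2_fc": _log2_fold_change(af, ctl) if direction != "none" else 0.0,
            "p_value": p,
            "direction": direction,
        })
    result = pd.DataFrame(rows)
    if add_q_values and not result.empty:
        from statsmodels.stats.multitest import multipletests

        result["q_value"] = multipletests(
            result["p_value"], method="fdr_bh")[1]
    return result
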