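"""Potential bile-acid-producer genera and the enzyme-genus network.

A genus is called a *potential producer* of UDCA, LCA or DCA when it
harbours at least one gene for an enzyme of the corresponding synthesis
pathway.  Two further summaries follow the field's conventions: genera
carrying both 7alpha- and 7beta-HSDH (the full CDCA<->UDCA epimerisation
pair) and genera carrying a near-complete bai operon (>= 5 distinct bai
genes by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import (
    BAI_GENES,
    DEFAULT_BAI_MIN_COUNT,
    DEFAULT_PATHWAYS,
    ENZYMES,
    HSDH_ALPHA,
    HSDH_BETA,
)
from .profiling import genus_of

logger = logging.getLogger(__name__)


@dataclass
class GenusEnzymeMatrix:
    """Genus x enzyme gene counts plus per-(genus, enzyme) sample abundances.

    ``counts`` is a genus x enzyme integer frame; ``abundance`` is indexed
    by (genus, enzyme) with one column per sample, holding the summed
    relative abundance of the member genes.
    """

    counts: pd.DataFrame
    abundance: pd.DataFrame

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


@dataclass
class PathwayMap:
    """Enzyme membership of the three secondary-BA synthesis pathways."""

    pathways: dict[str, frozenset[str]] = field(
        default_factory=lambda: {k: frozenset(v) for k, v in DEFAULT_PATHWAYS.items()})
    bai_set: frozenset[str] = frozenset(BAI_GENES)
    bai_min_count: int = DEFAULT_BAI_MIN_COUNT

    def __post_init__(self) -> None:
        known = set(ENZYMES)
        for name, enzymes in self.pathways.items():
            unknown = set(enzymes) - known
            if unknown:
                raise ValueError(
                    f"pathway {name!r} references unknown enzymes: {sorted(unknown)}")
        if not 1 <= self.bai_min_count <= len(self.bai_set):
            raise ValueError("bai_min_count out of range")


@dataclass
class ProducerReport:
    """Producer-genus sets and their Venn decomposition."""

    pathway_sets: dict[str, set[str]]
    venn_counts: dict[str, int]
    hsdh_pair_set: set[str]
    bai_complete_set: set[str]

    def counts(self) -> dict[str, int]:
        out = {name: len(s) for name, s in self.pathway_sets.items()}
        out["hsdh_pair"] = len(self.hsdh_pair_set)
        out["bai_complete"] = len(self.bai_complete_set)
        return out


def build_genus_enzyme_matrix(
    assignments: Mapping[str, str],
    lineages: Mapping[str, tuple[str, ...]],
    abundance: pd.DataFrame,
) -> GenusEnzymeMatrix:
    """Aggregate enzyme genes by their taxonomic-LCA genus.

    Genes whose LCA resolves above genus carry no genus attribution and are
    excluded here (they remain in the enzyme profile).
    """
    rows = []
    for gene, enzyme in assignments.items():
        genus = genus_of(lineages.get(gene, ()))
        if genus is not None:
            rows.append((genus, enzyme, gene))
    if not rows:
        empty = pd.DataFrame(columns=list(ENZYMES))
        return GenusEnzymeMatrix(empty, pd.DataFrame(columns=abundance.columns))
    frame = pd.DataFrame(rows, columns=["genus", "enzyme", "gene_id"])
    counts = (
        frame.groupby(["genus", "enzyme"]).size().unstack(fill_value=0)
        .reindex(columns=list(ENZYMES), fill_value=0)
    )
    abund = (
        abundance.loc[frame["gene_id"]]
        .set_axis(pd.MultiIndex.from_frame(frame[["genus", "enzyme"]]))
        .groupby(level=["genus", "enzyme"]).sum()
    )
    return GenusEnzymeMatrix(counts, abund)


def _venn_regions(sets: dict[str, set[str]]) -> dict[str, int]:
    """Disjoint region sizes of the Venn diagram over the given sets."""
    names = list(sets)
    regions: dict[str, int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            regions["&".join(combo)] = len(inside)
    return regions


def classify_producers(
    matrix: GenusEnzymeMatrix,
    pathway_map: PathwayMap | None = None,
) -> ProducerReport:
    """Call producer genera per pathway plus the HSDH-pair and bai sets."""
    pm = pathway_map or PathwayMap()
    if matrix.counts.empty:
        raise ValueError("empty genus-enzyme matrix")
    presence = matrix.presence
    pathway_sets = {
        name: set(presence.index[presence[list(enzymes)].any(axis=1)])
        for name, enzymes in pm.pathways.items()
    }
    hsdh_pair = set(
        presence.index[presence[HSDH_ALPHA] & presence[HSDH_BETA]])
    bai_cols = [e for e in pm.bai_set if e in presence.columns]
    bai_complete = set(
        presence.index[presence[bai_cols].sum(axis=1) >= pm.bai_min_count])
    return ProducerReport(
        pathway_sets=pathway_sets,
        venn_counts=_venn_regions(pathway_sets),
        hsdh_pair_set=hsdh_pair,
        bai_complete_set=bai_complete,
    )


def correlation_network(
    genus_abundance: pd.DataFrame,
    enzyme_profile: pd.DataFrame,
    method: str = "spearman",
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Signed genus-enzyme correlation edges below the p threshold.

    Both tables are feature x sample over the same samples; pairs where
    either vector is constant are skipped with a logged warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method}")
    samples = genus_abundance.columns
    if not samples.equals(enzyme_profile.columns):
        raise ValueError("sample columns differ between the two tables")
    if len(samples) < 4:
        raise ValueError("need at least 4 samples for the network")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    edges = []
    for genus, gvals in genus_abundance.iterrows():
        g = gvals.to_numpy(dtype=float)
        if np.all(g == g[0]):
            logger.warning("skipping constant genus vector: %s", genus)
            continue
        for enzyme, evals_ in enzyme_profile.iterrows():
            e = evals_.to_numpy(dtype=float)
            if np.all(e == e[0]):
                logger.warning("skipping constant enzyme vector: %s", enzyme)
                continue
            rho, p = corr(g, e)
            if p < p_threshold:
                edges.append({
                    "genus": genus, "enzyme": enzyme,
                    "rho": float(rho), "p_value": float(p),
                    "sign": "positive" if rho > 0 else "negative",
                })
    return pd.DataFrame(
        edges, columns=["genus", "enzyme", "rho", "p_value", "sign"])


def network_to_graphml(edges: pd.DataFrame, path) -> None:
    """Write the edge list as GraphML for network viewers."""
    import networkx as nx

    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_node(row.genus, kind="genus")
        graph.add_node(row.enzyme, kind="enzyme")
        graph.add_edge(
            row.genus, row.enzyme, rho=row.rho, p_value=row.p_value,
            sign=row.sign)
    nx.write_graphml(graph, path)
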