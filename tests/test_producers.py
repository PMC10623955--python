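"""Producer-genus classification and the enzyme-genus correlation network."""

import numpy as np
import pandas as pd
import pytest

from bileaxis import (
    DEFAULT_PATHWAYS,
    GenusEnzymeMatrix,
    PathwayMap,
    assign_enzyme,
    build_genus_enzyme_matrix,
    classify_producers,
    correlation_network,
    filter_significant_hits,
    lca_assign,
)
from bileaxis.vocab import ENZYMES, genus_lineage


def _matrix(counts: dict[str, dict[str, int]]) -> GenusEnzymeMatrix:
    frame = pd.DataFrame(counts).T.reindex(columns=list(ENZYMES), fill_value=0)
    return GenusEnzymeMatrix(frame.fillna(0).astype(int), pd.DataFrame())


def test_counts_and_presence_from_gene_assignments():
    abundance = pd.DataFrame(
        {"s1": [0.1, 0.2, 0.3], "s2": [0.3, 0.2, 0.1]},
        index=["g1", "g2", "g3"])
    assignments = {"g1": "BaiH", "g2": "BaiH", "g3": "BSH"}
    lineages = {
        "g1": genus_lineage("Blautia"),
        "g2": genus_lineage("Blautia"),
        "g3": genus_lineage("Blautia")[:4],  # resolves at order only
    }
    m = build_genus_enzyme_matrix(assignments, lineages, abundance)
    assert m.counts.loc["Blautia", "BaiH"] == 2
    assert m.presence.loc["Blautia", "BaiH"]
    assert m.counts.loc["Blautia", "BSH"] == 0  # above-genus gene excluded
    np.testing.assert_allclose(
        m.abundance.loc[("Blautia", "BaiH")], [0.3, 0.5])


def test_matrix_matches_truth_on_synthetic_metagenome(metagenome):
    table, hits = metagenome["table"], metagenome["hits"]
    truth = metagenome["truth"]
    assignments = assign_enzyme(filter_significant_hits(hits))
    lineages = lca_assign(metagenome["taxhits"])
    m = build_genus_enzyme_matrix(assignments, lineages, table.abundance)
    expected = {}
    for gene, enzyme in truth.gene_enzyme.items():
        genus = truth.gene_genus[gene]
        expected[(genus, enzyme)] = expected.get((genus, enzyme), 0) + 1
    for (genus, enzyme), count in expected.items():
        assert m.counts.loc[genus, enzyme] == count
    assert int(m.counts.to_numpy().sum()) == len(truth.gene_enzyme)


def test_classify_five_distinct_bai_genes_is_complete():
    m = _matrix({
        "Blautia": {"BaiB": 1, "BaiF": 1, "BaiA": 1, "BaiH": 1, "BaiCD": 1},
        "Dialister": {"7alpha-HSDH": 2},
    })
    report = classify_producers(m)
    assert "Blautia" in report.bai_complete_set
    assert report.pathway_sets["UDCA-synthesis"] == {"Dialister"}
    assert "Dialister" not in report.hsdh_pair_set


def test_unknown_pathway_enzyme_rejected():
    with pytest.raises(ValueError, match="unknown enzymes"):
        PathwayMap(pathways={"UDCA-synthesis": frozenset({"BaiZ"})})


def test_planted_counts_recovered_and_venn_regions_sum(metagenome):
    table, truth = metagenome["table"], metagenome["truth"]
    assignments = assign_enzyme(filter_significant_hits(metagenome["hits"]))
    lineages = lca_assign(metagenome["taxhits"])
    m = build_genus_enzyme_matrix(assignments, lineages, table.abundance)
    report = classify_producers(m)
    assert report.counts() == truth.producer_counts(DEFAULT_PATHWAYS)
    union = set().union(*report.pathway_sets.values())
    assert sum(report.venn_counts.values()) == len(union)
    # bai-complete genera necessarily produce LCA/DCA under the default map
    assert report.bai_complete_set <= (
        report.pathway_sets["LCA-synthesis"] | report.pathway_sets["DCA-synthesis"])


class TestNetwork:
    samples = [f"s{i}" for i in range(10)]

    def test_perfect_monotone_pair_gives_rho_one(self):
        x = np.arange(10.0)
        genus = pd.DataFrame([x], index=["Blautia"], columns=self.samples)
        enzyme = pd.DataFrame([np.exp(x)], index=["BaiH"], columns=self.samples)
        edges = correlation_network(genus, enzyme)
        assert edges.loc[0, "rho"] == pytest.approx(1.0)
        assert edges.loc[0, "sign"] == "positive"

    def test_anti_monotone_pair_negative(self):
        x = np.arange(10.0)
        genus = pd.DataFrame([x], index=["Blautia"], columns=self.samples)
        enzyme = pd.DataFrame([-x ** 3], index=["BaiH"], columns=self.samples)
        edges = correlation_network(genus, enzyme)
        assert edges.loc[0, "rho"] == pytest.approx(-1.0)
        assert edges.loc[0, "sign"] == "negative"

    def test_spearman_invariant_under_monotone_transform(self, rng):
        g = rng.random((3, 12))
        e = rng.random((2, 12))
        cols = [f"s{i}" for i in range(12)]
        genus = pd.DataFrame(g, index=list("abc"), columns=cols)
        enzyme = pd.DataFrame(e, index=list("xy"), columns=cols)
        base = correlation_network(genus, enzyme, p_threshold=1.1)
        warped = correlation_network(
            np.exp(genus), enzyme ** 3, p_threshold=1.1)
        np.testing.assert_allclose(base["rho"], warped["rho"], atol=1e-12)

    def test_constant_vector_skipped(self, caplog):
        genus = pd.DataFrame(
            [[1.0] * 10], index=["Blautia"], columns=self.samples)
        enzyme = pd.DataFrame(
            [np.arange(10.0)], index=["BaiH"], columns=self.samples)
        with caplog.at_level("WARNING"):
            edges = correlation_network(genus, enzyme, p_threshold=1.1)
        assert edges.empty
        assert "constant" in caplog.text

    def test_null_pairs_pass_at_about_the_nominal_rate(self, rng):
        cols = [f"s{i}" for i in range(30)]
        genus = pd.DataFrame(rng.random((50, 30)), columns=cols)
        enzyme = pd.DataFrame(rng.random((40, 30)), columns=cols)
        edges = correlation_network(genus, enzyme, p_threshold=0.05)
        rate = len(edges) / (50 * 40)
        assert 0.02 < rate < 0.09
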