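"""Hit filtering, enzyme assignment, taxonomic LCA and Wilcoxon testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bileaxis import (
    assign_enzyme,
    compute_enzyme_profile,
    differential_features,
    filter_significant_hits,
    lca_assign,
    wilcoxon_rank_sum,
)
from bileaxis.vocab import RANKS, genus_lineage

from conftest import brute_force_filter, brute_force_lca, exhaustive_wilcoxon_p


def _hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "enzyme", "pident", "evalue", "bitscore"])


class TestHitFilter:
    def test_threshold_is_inclusive_ten_times_minimum(self):
        hits = _hits([
            ("g1", "BaiH", 90, 1e-20, 500),
            ("g1", "BaiB", 80, 5e-20, 400),
            ("g1", "BaiF", 70, 2e-19, 300),
        ])
        kept = filter_significant_hits(hits)
        assert set(kept["evalue"]) == {1e-20, 5e-20}

    def test_single_hit_retained_and_empty_passthrough(self):
        one = _hits([("g1", "BSH", 90, 1e-8, 100)])
        assert len(filter_significant_hits(one)) == 1
        assert filter_significant_hits(one.iloc[:0]).empty

    def test_zero_evalue_does_not_exclude_everything(self):
        hits = _hits([("g1", "BaiH", 99, 0.0, 900),
                      ("g1", "BaiB", 70, 1e-300, 400)])
        kept = filter_significant_hits(hits)
        assert len(kept) == 1  # 1e-300 > 10 * 1e-308

    def test_idempotent(self, rng):
        hits = _hits([
            (f"g{i % 50}", "BSH", 80, 10.0 ** rng.uniform(-180, -5), 100)
            for i in range(400)])
        once = filter_significant_hits(hits)
        twice = filter_significant_hits(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-180, max_value=-1), min_size=1, max_size=15),
           st.floats(min_value=0.5, max_value=100))
    def test_matches_brute_force_for_any_factor(self, exps, factor):
        ev = [10.0 ** e for e in exps]
        hits = _hits([("g", "BSH", 80, e, 100) for e in ev])
        kept = filter_significant_hits(hits, factor=factor)
        expect = brute_force_filter(ev, factor)
        assert sorted(kept["evalue"]) == sorted(np.asarray(ev)[expect])


class TestAssignEnzyme:
    def test_best_hit_by_lowest_evalue(self):
        hits = _hits([("g1", "BaiH", 90, 1e-50, 500),
                      ("g1", "BaiCD", 80, 1e-10, 400)])
        assert assign_enzyme(hits) == {"g1": "BaiH"}

    def test_bitscore_then_name_break_ties(self):
        hits = _hits([("g1", "BaiCD", 90, 1e-50, 150),
                      ("g1", "BaiH", 90, 1e-50, 200)])
        assert assign_enzyme(hits) == {"g1": "BaiH"}
        hits = _hits([("g1", "BaiH", 90, 1e-50, 200),
                      ("g1", "BaiCD", 90, 1e-50, 200)])
        assert assign_enzyme(hits) == {"g1": "BaiCD"}

    def test_no_hits_unassigned(self):
        assert assign_enzyme(_hits([])) == {}


class TestEnzymeProfile:
    def test_sums_member_gene_abundances(self):
        abundance = pd.DataFrame(
            {"s1": [0.01, 0.02, 0.5]}, index=["g1", "g2", "g3"])
        profile = compute_enzyme_profile(
            {"g1": "7alpha-HSDH", "g2": "7alpha-HSDH"}, abundance,
            enzymes=["7alpha-HSDH", "BaiI"])
        assert profile.loc["7alpha-HSDH", "s1"] == pytest.approx(0.03)
        assert profile.loc["BaiI", "s1"] == 0.0

    def test_missing_gene_raises_with_name(self):
        abundance = pd.DataFrame({"s1": [0.1]}, index=["g1"])
        with pytest.raises(KeyError, match="ghost"):
            compute_enzyme_profile({"ghost": "BSH"}, abundance)

    def test_matches_brute_force_summation_and_conserves_mass(self, rng):
        genes = [f"g{i}" for i in range(500)]
        abundance = pd.DataFrame(
            rng.dirichlet(np.ones(500), size=8).T, index=genes,
            columns=[f"s{i}" for i in range(8)])
        enzymes = ["BSH", "BaiH", "BaiCD", "7beta-HSDH"]
        assignments = {g: enzymes[i % 4] for i, g in enumerate(genes) if i % 3 == 0}
        profile = compute_enzyme_profile(assignments, abundance, enzymes=enzymes)
        for e in enzymes:
            members = [g for g, a in assignments.items() if a == e]
            np.testing.assert_allclose(
                profile.loc[e], abundance.loc[members].sum(axis=0))
        assert (profile.sum(axis=0) <= 1 + 1e-12).all()


class TestLca:
    @staticmethod
    def _tax(rows):
        return pd.DataFrame(rows, columns=["gene_id", "evalue", *RANKS])

    def test_agreeing_genus_hits_resolve_to_genus(self):
        lin = genus_lineage("Blautia")
        tax = self._tax([("g1", 1e-30, *lin), ("g1", 2e-30, *lin)])
        assert lca_assign(tax)["g1"] == lin

    def test_two_genera_same_family_back_off_one_rank(self):
        a = genus_lineage("Blautia")       # Lachnospiraceae
        b = genus_lineage("Roseburia")     # Lachnospiraceae
        tax = self._tax([("g1", 1e-30, *a), ("g1", 2e-30, *b)])
        assert lca_assign(tax)["g1"] == a[:5]

    def test_superkingdom_disagreement_is_root(self):
        a = genus_lineage("Blautia")
        b = ("Archaea",) + a[1:]
        tax = self._tax([("g1", 1e-30, *a), ("g1", 2e-30, *b)])
        assert lca_assign(tax)["g1"] == ()

    def test_decoys_beyond_10x_are_ignored(self):
        a = genus_lineage("Blautia")
        b = genus_lineage("Bacteroides")
        tax = self._tax([("g1", 1e-30, *a), ("g1", 1e-28, *b)])
        assert lca_assign(tax)["g1"] == a

    def test_malformed_lineage_rejected(self):
        row = list(genus_lineage("Blautia"))
        row[3] = ""  # missing order above a named family
        tax = self._tax([("g1", 1e-30, *row)])
        with pytest.raises(ValueError, match="malformed"):
            lca_assign(tax)


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exhaustive_wilcoxon_p(
            np.array([1., 2, 3]), np.array([4., 5, 6])), abs=1e-12)

    def test_identical_groups_p_one_fc_zero(self):
        table = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]],
                             index=["f"], columns=list("abcdef"))
        groups = pd.Series(["AF"] * 3 + ["control"] * 3, index=list("abcdef"))
        res = differential_features(table, groups)
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2_fc"] == 0.0
        assert res.loc[0, "direction"] == "none"

    def test_small_group_errors(self):
        table = pd.DataFrame([[1.0, 2, 3]], index=["f"], columns=list("abc"))
        groups = pd.Series(["AF", "AF", "control"], index=list("abc"))
        with pytest.raises(ValueError):
            differential_features(table, groups)

    def test_direction_tracks_median_difference(self, rng):
        af = rng.lognormal(1.0, 0.3, 20)
        ctl = rng.lognormal(0.0, 0.3, 20)
        table = pd.DataFrame([np.concatenate([af, ctl])], index=["f"])
        groups = pd.Series(["AF"] * 20 + ["control"] * 20, index=table.columns)
        res = differential_features(table, groups)
        assert res.loc[0, "direction"] == "up"
        assert res.loc[0, "log2_fc"] > 0

    def test_optional_bh_column(self, rng):
        table = pd.DataFrame(rng.normal(size=(5, 12)))
        groups = pd.Series(["AF"] * 6 + ["control"] * 6, index=table.columns)
        res = differential_features(table, groups, add_q_values=True)
        assert "q_value" in res
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
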