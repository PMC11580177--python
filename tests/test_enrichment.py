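import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from fluxdiff.enrichment import (GeneSetCollection, crossref_gene_list,
                                 merge_regulated_lists, ora,
                                 overlap_directional, read_gmt, write_gmt)
from fluxdiff.proteomics import DifferentialResult


class TestGMT:
    def test_roundtrip(self, tmp_path):
        coll = GeneSetCollection(
            {"S1": frozenset({"a", "b"}), "S2": frozenset({"b", "c", "d"})},
            {"S1": "first", "S2": "second"})
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_duplicate_members_stored_once(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tdesc\ta\tb\ta\n")
        coll = read_gmt(path)
        assert coll.sets["S1"] == {"a", "b"}

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\ta\nS2\tdesc-only\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)

    def test_universe_is_union_of_members(self, tmp_path):
        path = tmp_path / "u.gmt"
        path.write_text("S1\td\ta\tb\nS2\td\tb\tc\n")
        assert read_gmt(path).universe == {"a", "b", "c"}


class TestMerge:
    def test_union_with_source_tags(self):
        merged = merge_regulated_lists({"a", "b"}, {"b", "c"})
        tags = dict(zip(merged["id"], merged["source"]))
        assert tags == {"a": "dfba", "b": "both", "c": "imat"}

    def test_empty_side(self):
        merged = merge_regulated_lists(set(), {"x"})
        assert list(merged["id"]) == ["x"]
        assert list(merged["source"]) == ["imat"]

    def test_inclusion_exclusion_count(self):
        # 70 and 88 with 3 shared -> 155 merged
        a = {f"a{i}" for i in range(67)} | {"s1", "s2", "s3"}
        b = {f"b{i}" for i in range(85)} | {"s1", "s2", "s3"}
        assert len(merge_regulated_lists(a, b)) == 155

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=st.sets(st.sampled_from("abcdefgh")),
           b=st.sets(st.sampled_from("abcdefgh")))
    def test_merge_commutative_and_idempotent(self, a, b):
        ab = merge_regulated_lists(a, b)
        ba = merge_regulated_lists(b, a)
        assert set(ab["id"]) == set(ba["id"])
        both = set(ab.loc[ab["source"] == "both", "id"])
        assert both == set(ba.loc[ba["source"] == "both", "id"]) == (a & b)
        again = merge_regulated_lists(set(ab["id"]), set(ab["id"]))
        assert set(again["id"]) == set(ab["id"])


class TestORA:
    def test_exact_hypergeometric_probability(self):
        # query of 5 hitting all 5 members of a set in a universe of 20:
        # p = 1 / C(20,5) = 1/15504
        universe = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        coll = GeneSetCollection({"S": frozenset(members)}, {"S": ""})
        res = ora(members, coll, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0 / 15504, rel=1e-12)
        assert res.loc[0, "k"] == 5

    def test_query_equal_universe_forces_full_overlap_p1(self):
        universe = {f"g{i}" for i in range(10)}
        coll = GeneSetCollection({"S": frozenset(list(universe)[:4])}, {"S": ""})
        res = ora(universe, coll, universe)
        assert res.loc[0, "k"] == 4  # overlap = K
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_min_overlap_excludes_small_hits(self):
        universe = {f"g{i}" for i in range(40)}
        members = {"g0", "g1", "g2"}
        coll = GeneSetCollection({"S": frozenset(members)}, {"S": ""})
        res = ora(members, coll, universe, min_overlap=4)
        assert res.loc[0, "p"] < 1e-3          # k = 3, p tiny
        assert not res.loc[0, "significant"]   # but below the overlap floor

    def test_query_outside_universe_dropped(self):
        universe = {"a", "b", "c", "d"}
        coll = GeneSetCollection({"S": frozenset({"a", "b"})}, {"S": ""})
        res = ora({"a", "zzz"}, coll, universe)
        assert res.loc[0, "n"] == 1

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection({"S": frozenset({"a"})}, {"S": ""})
        with pytest.raises(ValueError, match="universe"):
            ora({"a"}, coll, set())

    def test_p_matches_fisher_exact_upper_tail(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            members = set(rng.choice(universe, K, replace=False))
            query = set(rng.choice(universe, n, replace=False))
            k = len(members & query)
            coll = GeneSetCollection({"S": frozenset(members)}, {"S": ""})
            res = ora(query, coll, set(universe))
            table = [[k, len(query) - k],
                     [len(members) - k, N - len(members) - len(query) + k]]
            _, p_fisher = fisher_exact(table, alternative="greater")
            assert res.loc[0, "p"] == pytest.approx(p_fisher, rel=1e-9)

    def test_bh_fdr_monotone_after_sorting(self):
        rng = np.random.default_rng(1)
        universe = {f"g{i}" for i in range(50)}
        sets = {f"S{j}": frozenset(rng.choice(sorted(universe), 8,
                                              replace=False))
                for j in range(20)}
        coll = GeneSetCollection(sets, {k: "" for k in sets})
        query = set(rng.choice(sorted(universe), 12, replace=False))
        res = ora(query, coll, universe)
        assert (res["fdr"].to_numpy()[1:] >= res["fdr"].to_numpy()[:-1] - 1e-12).all()
        assert (res["fdr"] >= res["p"] - 1e-12).all()


def _diff(proteins, logfc, pvals):
    tab = pd.DataFrame({"logFC": logfc, "AveExpr": 10.0, "s2": 1.0,
                        "s2_prior": 1.0, "s2_post": 1.0, "t": 1.0,
                        "P.Value": pvals}, index=proteins)
    return DifferentialResult(tab, 4.0, 1.0, ("control", "treatment"))


class TestOverlapAndCrossref:
    def test_shared_down_counted(self):
        a = _diff(["p", "q", "r"], [-1, -1, 1], [0.01, 0.01, 0.5])
        b = _diff(["p", "q", "r"], [1, -1, -1], [0.5, 0.01, 0.01])
        tab = overlap_directional(a, b)
        down = tab[tab["direction"] == "down"].iloc[0]
        assert down["shared"] == 1          # q
        assert down["a_only"] == 1          # p
        assert down["b_only"] == 1          # r

    def test_no_significance_means_no_overlap(self):
        a = _diff(["p", "q"], [-1, -1], [0.9, 0.9])
        b = _diff(["p", "q"], [-1, -1], [0.01, 0.01])
        tab = overlap_directional(a, b)
        assert tab["shared"].sum() == 0

    def test_superset_plant_fully_overlaps(self):
        a = _diff(["p", "q", "r"], [-1, -1, -1], [0.01, 0.01, 0.9])
        b = _diff(["p", "q", "r"], [-1, -1, -1], [0.01, 0.01, 0.01])
        tab = overlap_directional(a, b)
        down = tab[tab["direction"] == "down"].iloc[0]
        assert down["shared"] == 2 and down["a_only"] == 0

    def test_crossref_empty_and_full_risk_sets(self):
        d = _diff(["p1", "p2"], [-1, 2], [0.01, 0.01])
        id_map = {"p1": "gA", "p2": "gB"}
        assert len(crossref_gene_list(d, set(), id_map)) == 0
        full = crossref_gene_list(d, {"gA", "gB"}, id_map)
        assert len(full) == 2
        assert set(full["direction"]) == {"down", "up"}

    def test_crossref_planted_subset(self):
        d = _diff(["p1", "p2", "p3"], [-1, -1, -1], [0.01, 0.01, 0.01])
        id_map = {"p1": "gA", "p2": "gB", "p3": "gC"}
        tab = crossref_gene_list(d, {"gB"}, id_map)
        assert list(tab["gene"]) == ["gB"]
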