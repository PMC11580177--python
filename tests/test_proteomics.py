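import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxdiff.proteomics import (AbundanceMatrix, dedupe_abundances,
                                 filter_peptides, moderated_diff,
                                 rollup_and_normalize,
                                 select_gene_fold_changes)


def _pep(rows):
    return pd.DataFrame(rows, columns=["peptide", "protein", "c1", "c2"])


class TestPeptideFilter:
    def test_boundary_at_threshold(self):
        table = _pep([("p1", "A", 100.0, 80.0),    # sums to 180 -> kept
                      ("p2", "A", 100.0, 79.5),    # 179.5 -> removed
                      ("p3", "B", 500.0, 0.0)])
        kept = filter_peptides(table, 180.0)
        assert list(kept["peptide"]) == ["p1", "p3"]

    def test_empty_table(self):
        assert len(filter_peptides(_pep([]))) == 0


class TestRollupNormalize:
    def test_column_sums_equalized_to_mean(self):
        # raw column sums (4, 8) -> both scaled to 6
        table = _pep([("p1", "A", 1.0, 3.0), ("p2", "B", 3.0, 5.0)])
        mat = rollup_and_normalize(table)
        assert np.allclose(mat.values.sum(axis=0), [6.0, 6.0])
        # within-column ratios preserved
        assert np.isclose(mat.values.loc["A", "c1"] / mat.values.loc["B", "c1"],
                          1.0 / 3.0)

    def test_peptides_summed_per_protein(self):
        table = pd.DataFrame({"peptide": ["p1", "p2"], "protein": ["A", "A"],
                              "c1": [100.0, 90.0]})
        mat = rollup_and_normalize(table)
        assert mat.values.loc["A", "c1"] == 190.0  # single channel: scale 1

    def test_zero_channel_is_error(self):
        table = _pep([("p1", "A", 1.0, 0.0)])
        with pytest.raises(ValueError, match="c2"):
            rollup_and_normalize(table)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.5, 1e4), st.floats(0.5, 1e4),
                              st.floats(0.5, 1e4)),
                    min_size=2, max_size=12))
    def test_normalized_column_sums_always_equal(self, vals):
        table = pd.DataFrame(
            [{"peptide": f"p{i}", "protein": f"P{i}",
              "c1": a, "c2": b, "c3": c} for i, (a, b, c) in enumerate(vals)])
        mat = rollup_and_normalize(table)
        sums = mat.values.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums[0], rtol=1e-9)


def _matrix(data, n_ctrl=3, n_trt=3):
    cols = [f"ctrl_{i}" for i in range(n_ctrl)] + [f"trt_{i}" for i in range(n_trt)]
    design = {c: ("control" if c.startswith("ctrl") else "treatment")
              for c in cols}
    return AbundanceMatrix(pd.DataFrame(data, columns=cols), design)


class TestModeratedDiff:
    def test_identical_groups_give_null_stats(self):
        rng = np.random.default_rng(0)
        data = 2.0 ** rng.normal(10, 1, (20, 3))
        mat = _matrix(np.hstack([data, data]))
        res = moderated_diff(mat)
        assert np.allclose(res.table["logFC"], 0.0)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["P.Value"], 1.0)

    def test_prior_df_zero_recovers_ordinary_pooled_t(self):
        rng = np.random.default_rng(1)
        data = 2.0 ** rng.normal(10, 1, (30, 6))
        mat = _matrix(data)
        res = moderated_diff(mat, prior_df=0.0)
        x = np.log2(mat.values.to_numpy())
        xc, xt = x[:, :3], x[:, 3:]
        s2 = (((xc - xc.mean(1, keepdims=True)) ** 2).sum(1) +
              ((xt - xt.mean(1, keepdims=True)) ** 2).sum(1)) / 4
        t_ref = (xt.mean(1) - xc.mean(1)) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        assert np.allclose(res.table["t"], t_ref, rtol=1e-10)

    def test_prior_df_infinite_shrinks_fully_to_trend(self):
        rng = np.random.default_rng(2)
        data = 2.0 ** rng.normal(10, 1, (30, 6))
        res = moderated_diff(_matrix(data), prior_df=np.inf)
        assert np.allclose(res.table["s2_post"], res.table["s2_prior"])

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(3)
        data = 2.0 ** rng.normal(10, 1.5, (80, 6))
        res = moderated_diff(_matrix(data))
        lo = np.minimum(res.table["s2"], res.table["s2_prior"])
        hi = np.maximum(res.table["s2"], res.table["s2_prior"])
        assert ((res.table["s2_post"] >= lo - 1e-12) &
                (res.table["s2_post"] <= hi + 1e-12)).all()
        assert res.df_prior >= 0

    def test_group_swap_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(4)
        data = 2.0 ** rng.normal(10, 1, (40, 6))
        mat = _matrix(data)
        res = moderated_diff(mat)
        swapped = moderated_diff(mat, contrast=("treatment", "control"))
        assert np.allclose(res.table["logFC"], -swapped.table["logFC"])
        assert np.allclose(res.table["P.Value"], swapped.table["P.Value"])

    def test_small_group_is_design_error(self):
        mat = _matrix(2.0 ** np.random.default_rng(5).normal(10, 1, (5, 4)),
                      n_ctrl=1, n_trt=3)
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_diff(mat)


class TestLimmaOracle:
    """Frozen reference values computed with Bioconductor limma 3.58.1."""

    @staticmethod
    def _fixture():
        rng = np.random.default_rng(42)
        n = 60
        base = rng.normal(10, 1.5, n)
        sd = 0.1 + 0.3 * rng.random(n)
        lfc = np.zeros(n)
        lfc[:10] = rng.choice([-1.0, 1.0], 10)
        treat = np.array([0, 0, 0, 1, 1, 1])
        log2m = (base[:, None] + lfc[:, None] * treat[None, :]
                 + rng.normal(0, 1, (n, 6)) * sd[:, None])
        return _matrix(2.0 ** log2m)

    # eBayes(trend=FALSE, robust=FALSE): moments estimation matches exactly
    LIMMA_D0 = 4.330304128
    LIMMA_T = {  # protein row -> moderated t
        0: 4.083981734, 1: -5.25392715, 2: 0.808081649, 3: -5.531912802,
        4: 5.517666645, 5: -9.948545409, 6: -6.789587895, 7: -8.061386423,
        8: -5.49213566, 9: -7.191070964,
    }
    LIMMA_D0_TREND = 4.023728827  # eBayes(trend=TRUE): lowess details differ

    def test_constant_prior_matches_limma_exactly(self):
        res = moderated_diff(self._fixture(), trend=False)
        assert res.df_prior == pytest.approx(self.LIMMA_D0, rel=1e-8)
        for i, t_ref in self.LIMMA_T.items():
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, rel=1e-8)

    def test_trended_prior_close_to_limma(self):
        res = moderated_diff(self._fixture(), trend=True)
        assert res.df_prior == pytest.approx(self.LIMMA_D0_TREND, rel=0.15)
        t_const = moderated_diff(self._fixture(), trend=False).table["t"]
        assert np.corrcoef(res.table["t"], t_const)[0, 1] > 0.99


class TestFoldChangeSelection:
    @staticmethod
    def _result():
        tab = pd.DataFrame(
            {"logFC": [1.0, 2.0, -3.0, 0.5],
             "AveExpr": [10.0, 12.0, 9.0, 8.0],
             "s2": 1.0, "s2_prior": 1.0, "s2_post": 1.0,
             "t": [3.0, 4.0, -5.0, 1.0],
             "P.Value": [0.01, 0.20, 0.001, 0.04]},
            index=["prot_a1", "prot_a2", "prot_b", "prot_c"])
        from fluxdiff.proteomics import DifferentialResult
        return DifferentialResult(tab, 4.0, 1.0, ("control", "treatment"))

    ID_MAP = {"prot_a1": "gA", "prot_a2": "gA", "prot_b": "gB"}

    def test_min_p_keeps_most_significant_duplicate(self):
        fc = select_gene_fold_changes(self._result(), 0.05, self.ID_MAP, "min_p")
        assert fc == {"gA": 1.0, "gB": -3.0}  # p=0.20 duplicate not eligible

    def test_max_mean_keeps_highest_average(self):
        fc = select_gene_fold_changes(self._result(), 0.25, self.ID_MAP,
                                      "max_mean")
        assert fc["gA"] == 2.0  # AveExpr 12 beats 10

    def test_all_nonsignificant_gives_empty_mapping(self):
        fc = select_gene_fold_changes(self._result(), 1e-9, self.ID_MAP)
        assert fc == {}

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            select_gene_fold_changes(self._result(), 0.05, self.ID_MAP, "nope")


def test_dedupe_keeps_max_average_measurement():
    mat = AbundanceMatrix(
        pd.DataFrame({"s1": [10.0, 12.0, 5.0], "s2": [10.0, 12.0, 5.0]},
                     index=["prot_a1", "prot_a2", "prot_b"]))
    genes = dedupe_abundances(mat, {"prot_a1": "gA", "prot_a2": "gA",
                                    "prot_b": "gB"})
    assert genes.loc["gA", "s1"] == 12.0
    assert list(genes.index) == ["gA", "gB"]
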