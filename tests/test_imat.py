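import numpy as np
import pytest

from fluxdiff.bruteforce import enumerate_imat_objective, random_oracle_network
from fluxdiff.imat import (ActivityVector, InfeasibleModelError,
                           MandatoryBounds, classify_reactions,
                           consensus_differential, pca_binary, run_imat)
from fluxdiff.model_io import (MetabolicModel, Metabolite, Reaction, parse_gpr)


def _star_model():
    """->M (r1), M-> (r2), M-> (r3): r2 can be silenced while r1/r3 run."""
    return MetabolicModel(
        reactions=[Reaction("r1", lower_bound=0, upper_bound=10),
                   Reaction("r2", lower_bound=0, upper_bound=10),
                   Reaction("r3", lower_bound=0, upper_bound=10)],
        metabolites=[Metabolite("M")],
        stoichiometry=[("M", "r1", 1.0), ("M", "r2", -1.0), ("M", "r3", -1.0)],
        id="star")


class TestClassifyReactions:
    @staticmethod
    def _lone_gene_model(genes):
        return MetabolicModel(
            reactions=[Reaction(f"r_{g}", upper_bound=10, gpr=parse_gpr(g))
                       for g in genes],
            metabolites=[], stoichiometry=[])

    def test_quantile_thresholds_with_interpolation(self):
        # values 1..100: q25 = 25.75, q75 = 75.25 (linear interpolation)
        abund = {f"g{i}": float(i) for i in range(1, 101)}
        model = self._lone_gene_model(["g80", "g50", "g10"])
        r_high, r_low = classify_reactions(model, abund)
        assert r_high == {"r_g80"}
        assert r_low == {"r_g10"}

    def test_all_equal_abundances_classify_nothing(self):
        abund = {f"g{i}": 5.0 for i in range(10)}
        model = self._lone_gene_model(["g1", "g2"])
        r_high, r_low = classify_reactions(model, abund)
        assert r_high == set() and r_low == set()

    def test_external_proteome_sets_thresholds(self):
        # the same gene value classifies differently against a different
        # whole-proteome distribution
        model = self._lone_gene_model(["g1"])
        high, _ = classify_reactions(model, {"g1": 10.0},
                                     proteome=np.arange(1, 9, dtype=float))
        assert high == {"r_g1"}
        high2, low2 = classify_reactions(model, {"g1": 10.0},
                                         proteome=np.arange(20, 40, dtype=float))
        assert high2 == set() and low2 == {"r_g1"}

    def test_planted_low_branch_classified_low(self, toy):
        model, truth = toy
        abund = {g: (2.0 if g in truth.de_genes else 10.0)
                 for g in model.genes}
        proteome = np.concatenate([np.full(50, 10.0),
                                   list(abund.values())])
        _, r_low = classify_reactions(model, abund, proteome=proteome)
        assert truth.off_reactions <= r_low

    def test_empty_abundances_rejected(self, toy):
        model, _ = toy
        with pytest.raises(ValueError, match="empty"):
            classify_reactions(model, {})


class TestRunIMAT:
    def test_star_network_silences_low_keeps_high(self):
        flux, activity, context = run_imat(
            _star_model(), r_high=["r1", "r3"], r_low=["r2"], bounds=None)
        assert abs(flux["r2"]) <= 1e-6 + 1e-7
        assert flux["r1"] >= 1e-2 - 1e-7 and flux["r3"] >= 1e-2 - 1e-7
        assert activity == {"r1": 1, "r2": 0, "r3": 1}
        assert [r.id for r in context.reactions] == ["r1", "r3"]

    def test_objective_matches_enumeration(self):
        from fluxdiff.imat import imat_objective_from_flux
        for seed in range(8):
            model, _, rh, rl = random_oracle_network(seed)
            flux, _, _ = run_imat(model, rh, rl, bounds=None)
            got = imat_objective_from_flux(flux, rh, rl)
            assert got == enumerate_imat_objective(model, rh, rl)

    def test_no_classification_keeps_everything(self):
        flux, activity, context = run_imat(_star_model(), [], [], bounds=None)
        assert all(a == 1 for a in activity.values())
        assert len(context.reactions) == 3

    def test_essential_low_reaction_stays_active(self):
        """A low reaction on the only path to biomass cannot be removed."""
        model = MetabolicModel(
            reactions=[Reaction("r_in", lower_bound=0, upper_bound=10),
                       Reaction("r_mid", lower_bound=0, upper_bound=10),
                       Reaction("r_bm", lower_bound=0, upper_bound=10)],
            metabolites=[Metabolite("A"), Metabolite("B")],
            stoichiometry=[("A", "r_in", 1.0), ("A", "r_mid", -1.0),
                           ("B", "r_mid", 1.0), ("B", "r_bm", -1.0)],
            biomass_id="r_bm", id="line")
        bounds = MandatoryBounds(biomass_min=1e-3)
        flux, activity, context = run_imat(model, [], ["r_mid"], bounds)
        assert flux["r_mid"] >= 1e-3 - 1e-9
        assert activity["r_mid"] == 1
        assert len(context.reactions) == 3

    def test_overlapping_classification_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            run_imat(_star_model(), ["r1"], ["r1"], bounds=None)

    def test_infeasible_mandatory_bounds_detected(self):
        model = _star_model()
        model.biomass_id = "r2"
        model.reactions[1].upper_bound = 1e-6
        with pytest.raises(InfeasibleModelError):
            run_imat(model, [], [], MandatoryBounds(biomass_min=1.0))

    def test_mandatory_bounds_validation(self):
        with pytest.raises(ValueError):
            MandatoryBounds(biomass_min=-1.0)
        with pytest.raises(ValueError):
            MandatoryBounds(ngam_relax_fraction=1.5)
        assert MandatoryBounds().ngam_min == pytest.approx(4.275)


def _av(sample, group, bits, rids=("a", "b", "c")):
    return ActivityVector(sample, group, dict(zip(rids, bits)))


class TestConsensus:
    def test_unanimous_loss_detected(self):
        ctrl = [_av(f"c{i}", "control", (1, 1, 1)) for i in range(3)]
        trt = [_av(f"t{i}", "treatment", (0, 1, 1)) for i in range(3)]
        res = consensus_differential(ctrl, trt)
        assert res.lost_in_treatment == {"a"}
        assert res.gained_in_treatment == set()

    def test_non_unanimous_is_not_differential(self):
        ctrl = [_av("c0", "control", (1, 1, 1)),
                _av("c1", "control", (1, 1, 1)),
                _av("c2", "control", (0, 1, 1))]
        trt = [_av(f"t{i}", "treatment", (0, 1, 1)) for i in range(3)]
        assert consensus_differential(ctrl, trt).differential == set()

    def test_inactive_everywhere_not_differential(self):
        ctrl = [_av(f"c{i}", "control", (0, 1, 1)) for i in range(3)]
        trt = [_av(f"t{i}", "treatment", (0, 1, 1)) for i in range(3)]
        assert consensus_differential(ctrl, trt).differential == set()

    def test_group_swap_exchanges_directions(self):
        ctrl = [_av(f"c{i}", "control", (1, 0, 1)) for i in range(3)]
        trt = [_av(f"t{i}", "treatment", (0, 1, 1)) for i in range(3)]
        a = consensus_differential(ctrl, trt)
        b = consensus_differential(trt, ctrl)
        assert a.lost_in_treatment == b.gained_in_treatment
        assert a.gained_in_treatment == b.lost_in_treatment

    def test_mismatched_universe_rejected(self):
        ctrl = [_av("c0", "control", (1, 1, 1))]
        trt = [_av("t0", "treatment", (1, 1), rids=("a", "b"))]
        with pytest.raises(ValueError, match="mismatched"):
            consensus_differential(ctrl, trt)


class TestPCABinary:
    def test_identical_samples_have_zero_scores(self):
        vecs = [_av("s1", "g", (1, 0, 1)), _av("s2", "g", (1, 0, 1))]
        scores, explained = pca_binary(vecs)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_pc1_separates_groups_differing_in_one_branch(self):
        rids = tuple(f"r{i}" for i in range(6))
        ctrl = [_av(f"c{i}", "control", (1, 1, 1, 1, 1, 1), rids)
                for i in range(3)]
        trt = [_av(f"t{i}", "treatment", (0, 0, 1, 1, 1, 1), rids)
               for i in range(3)]
        scores, explained = pca_binary(ctrl + trt)
        pc1 = scores["PC1"].to_numpy()
        assert np.sign(pc1[:3]).tolist() == [-np.sign(pc1[3])] * 3
        assert explained[0] == pytest.approx(1.0)

    def test_explained_variance_matches_covariance_eigenvalues(self):
        rng = np.random.default_rng(0)
        rids = tuple(f"r{i}" for i in range(10))
        vecs = [_av(f"s{i}", "g", tuple(rng.integers(0, 2, 10)), rids)
                for i in range(5)]
        scores, explained = pca_binary(vecs)
        X = np.array([[v.activity[r] for r in rids] for v in vecs], float)
        X = X[:, X.any(axis=0)]
        X = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        frac = eig[:len(explained)] / eig.sum()
        assert np.allclose(explained, frac, atol=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            pca_binary([_av("s1", "g", (1, 0, 1))])
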