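import math

import numpy as np
import pytest
from scipy.linalg import expm

from cultrait.mk import (
    MkAncestralStates,
    MkError,
    MkModel,
    asymmetric_lrt,
    fit_mk1,
    marginal_asr,
    pruning_loglik,
    support_ratio,
    transition_matrix,
)
from cultrait.pagel import simulate_binary
from cultrait.simulate import SimConfig, simulate_tree
from cultrait.supertree import enumerate_unrooted_topologies
from cultrait.tree import parse_newick
from .conftest import brute_force_loglik, random_binary_states


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        P = transition_matrix(MkModel(0.3, 0.7), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_mk1_closed_form_value(self):
        P = transition_matrix(MkModel.mk1(0.5), 1.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - math.exp(-1.0)), abs=1e-12)

    def test_long_time_reaches_stationary(self):
        m = MkModel(0.4, 0.1)
        P = transition_matrix(m, 1e6)
        for row in P:
            assert np.allclose(row, m.stationary(), atol=1e-12)

    def test_rows_stochastic_and_match_expm(self):
        for q01, q10 in [(1e-6, 1e-6), (0.01, 0.5), (2.0, 0.3), (10.0, 10.0)]:
            m = MkModel(q01, q10)
            for t in [0.0, 0.01, 1.0, 17.3, 100.0]:
                P = transition_matrix(m, t)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
                assert np.allclose(P, expm(m.rate_matrix() * t), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(MkError):
            transition_matrix(MkModel.mk1(0.1), -1.0)


class TestPruning:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        topos = enumerate_unrooted_topologies(taxa)
        tree = topos[rng.integers(0, len(topos))]
        for nd in tree.preorder():
            if nd.parent is not None:
                nd.length = float(rng.uniform(0.05, 3.0))
        model = MkModel(float(rng.uniform(0.05, 1.0)),
                        float(rng.uniform(0.05, 1.0)))
        tips = random_binary_states(taxa, rng, missing_frac=0.2)
        ll = pruning_loglik(tree, tips, model)
        bf = brute_force_loglik(tree, tips, model.rate_matrix(),
                                model.root_prior_vector())
        assert ll == pytest.approx(bf, abs=1e-10)

    def test_rate_to_zero_constant_tips(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        ll = pruning_loglik(tree, {"A": 1, "B": 1, "C": 1}, MkModel.mk1(1e-8))
        assert ll == pytest.approx(math.log(0.5), abs=1e-5)

    def test_unscored_leaf_rejected(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(MkError, match="missing"):
            pruning_loglik(tree, {"A": 1, "B": 0}, MkModel.mk1(0.1))


class TestFitMk1:
    def test_constant_character_hits_rate_floor(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        model, ll, _ = fit_mk1(tree, {"A": 1, "B": 1, "C": 1})
        assert model.q01 <= 1e-6

    def test_optimum_matches_grid_search(self, study_shallow):
        tree, matrix, _ = study_shallow
        tips = matrix.states_dict("afterlife")
        model, ll, _ = fit_mk1(tree, tips)
        grid = np.exp(np.linspace(np.log(1e-6), np.log(1.0), 400))
        lls = [pruning_loglik(tree, tips, MkModel.mk1(q)) for q in grid]
        assert ll >= max(lls) - 1e-6
        assert abs(math.log(model.q01) - math.log(grid[int(np.argmax(lls))])) < 0.1

    def test_parameter_recovery_within_25pct(self):
        cfg = SimConfig(n_taxa=200, depth=100.0, seed=21)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(21)
        q_true = 0.02
        tips = simulate_binary(tree, MkModel.mk1(q_true), rng)
        model, _, _ = fit_mk1(tree, tips)
        assert abs(model.q01 - q_true) / q_true < 0.25


class TestMarginalASR:
    def test_probabilities_sum_to_one_and_tips_certain(self, study_shallow):
        tree, matrix, _ = study_shallow
        tips = matrix.states_dict("shamanism")
        model, _, _ = fit_mk1(tree, tips)
        table = marginal_asr(tree, tips, model)
        assert np.allclose(table["p_absent"] + table["p_present"], 1.0,
                           atol=1e-9)
        for _, row in table[table["is_leaf"]].iterrows():
            s = tips[row["node"]]
            if s in (0, 1):
                assert row["p_present"] == pytest.approx(float(s), abs=1e-12)

    def test_mirror_symmetry_under_mk1(self, balanced4):
        for nd in balanced4.preorder():
            if nd.parent is not None:
                nd.length = 1.0
        tips = {"A": 1, "B": 0, "C": 1, "D": 0}
        flipped = {k: 1 - v for k, v in tips.items()}
        model = MkModel.mk1(0.3)
        t1 = marginal_asr(balanced4, tips, model)
        t2 = marginal_asr(balanced4, flipped, model)
        assert np.allclose(t1["p_present"], t2["p_absent"], atol=1e-12)

    def test_significance_flag_is_threshold_rule(self, study_shallow):
        tree, matrix, _ = study_shallow
        res = MkAncestralStates.from_matrix(tree, matrix, "animism").fit(
            threshold=2.0)
        root = res.ingroup_root("Outgroup")
        ratio = root["p_present"] / root["p_absent"]
        assert root["significant"] == (abs(math.log(ratio)) >= 2.0)

    def test_universal_trait_reconstructed_present_at_lca(self, study_shallow):
        # a trait present in every society reconstructs as ancestrally
        # present with overwhelming support, despite the absent outgroup
        tree, matrix, _ = study_shallow
        res = MkAncestralStates.from_matrix(tree, matrix, "animism").fit()
        root = res.ingroup_root("Outgroup")
        assert root["p_present"] > 0.95
        assert root["significant"]


class TestAsymmetryLRT:
    def test_lr_nonnegative_and_pvalue_valid(self, study_shallow):
        tree, matrix, _ = study_shallow
        for ch in ["afterlife", "high_gods"]:
            res = asymmetric_lrt(tree, matrix.states_dict(ch), seed=1)
            assert res.lr >= -1e-6
            assert 0.0 <= res.pvalue <= 1.0

    def test_type_i_error_controlled(self):
        # data generated under Mk1: the 2-rate model should rarely win
        cfg = SimConfig(n_taxa=64, depth=80.0, seed=5)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            tips = simulate_binary(tree, MkModel.mk1(0.02), rng)
            if asymmetric_lrt(tree, tips, seed=2).significant:
                rejections += 1
        assert rejections / n_rep <= 0.15

    def test_strong_asymmetry_detected(self):
        cfg = SimConfig(n_taxa=200, depth=100.0, seed=9)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            tips = simulate_binary(tree, MkModel(0.1, 0.01), rng)
            hits += asymmetric_lrt(tree, tips, seed=3).significant
        assert hits >= 6


def test_decision_threshold_support_ratio():
    # T = 2 corresponds to one state being ~7.4 times better supported
    assert support_ratio(2.0) == pytest.approx(7.389, abs=5e-4)
    assert round(support_ratio(2.0), 1) == 7.4
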