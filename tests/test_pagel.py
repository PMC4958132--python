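import dataclasses

import numpy as np
import pytest

from cultrait.mk import MkModel, pruning_loglik
from cultrait.pagel import (
    DEP_RATE_NAMES,
    PagelCorrelation,
    PagelError,
    dependent_rate_matrix,
    embed_independent,
    fit_pagel,
    independent_rate_matrix,
    joint_loglik,
    simulate_binary,
    simulate_joint,
)
from cultrait.simulate import SimConfig, simulate_tree
from cultrait.supertree import enumerate_unrooted_topologies
from cultrait.tree import parse_newick
from .conftest import brute_force_loglik, random_binary_states


def dependent_gain_matrix(base=0.02, boost=20.0):
    """B gains fast only when A is present; otherwise everything slow."""
    return dependent_rate_matrix(
        q12=base / boost, q13=base, q21=base, q24=base,
        q31=base / 4, q34=base * boost, q42=base / 4, q43=base / boost)


class TestJointLikelihood:
    def test_rate_matrix_rows_sum_to_zero(self):
        Q = dependent_rate_matrix(*np.random.default_rng(0).uniform(0.01, 1, 8))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)
        assert (Q - np.diag(np.diag(Q)) >= 0).all()

    def test_independent_model_factorises(self, balanced4):
        for nd in balanced4.preorder():
            if nd.parent is not None:
                nd.length = 1.3
        rng = np.random.default_rng(1)
        tipsA = random_binary_states(list("ABCD"), rng)
        tipsB = random_binary_states(list("ABCD"), rng)
        aG, aL, bG, bL = 0.3, 0.1, 0.2, 0.4
        joint = joint_loglik(balanced4, tipsA, tipsB,
                             independent_rate_matrix(aG, aL, bG, bL))
        sep = (pruning_loglik(balanced4, tipsA, MkModel(aG, aL, root_prior="uniform"))
               + pruning_loglik(balanced4, tipsB, MkModel(bG, bL, root_prior="uniform")))
        assert joint == pytest.approx(sep, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(4)]
        topos = enumerate_unrooted_topologies(taxa)
        tree = topos[rng.integers(0, len(topos))]
        for nd in tree.preorder():
            if nd.parent is not None:
                nd.length = float(rng.uniform(0.1, 2.0))
        Q = dependent_rate_matrix(*rng.uniform(0.02, 1.0, size=8))
        tipsA = random_binary_states(taxa, rng)
        tipsB = random_binary_states(taxa, rng)
        ll = joint_loglik(tree, tipsA, tipsB, Q)
        joint_states = {t: 2 * tipsA[t] + tipsB[t] for t in taxa}
        bf = brute_force_loglik(tree, joint_states, Q, np.full(4, 0.25))
        assert ll == pytest.approx(bf, abs=1e-10)

    def test_half_missing_tip_marginalises(self, balanced4):
        for nd in balanced4.preorder():
            if nd.parent is not None:
                nd.length = 1.0
        Q = dependent_rate_matrix(*np.random.default_rng(2).uniform(0.05, 1, 8))
        tipsA = {"A": -1, "B": 1, "C": 0, "D": 1}
        tipsB = {"A": 1, "B": 0, "C": 0, "D": 1}
        ll = joint_loglik(balanced4, tipsA, tipsB, Q)
        parts = [np.exp(joint_loglik(balanced4, dict(tipsA, A=s), tipsB, Q))
                 for s in (0, 1)]
        assert np.exp(ll) == pytest.approx(sum(parts), rel=1e-9)

    def test_unscored_leaf_rejected(self, balanced4):
        with pytest.raises(PagelError):
            joint_loglik(balanced4, {"A": 1}, {"A": 0},
                         independent_rate_matrix(0.1, 0.1, 0.1, 0.1))


class TestFitting:
    def test_nesting_on_random_datasets(self):
        rng = np.random.default_rng(4)
        for seed in range(6):
            tree = simulate_tree(SimConfig(n_taxa=12, depth=65.0, seed=seed))
            tipsA = random_binary_states(tree.leaf_labels, rng)
            tipsB = random_binary_states(tree.leaf_labels, rng)
            if len(set(tipsA.values())) < 2 or len(set(tipsB.values())) < 2:
                continue
            fit = fit_pagel(tree, tipsA, tipsB, seed=seed, n_starts=2,
                            iterations=200)
            assert fit.logL_d >= fit.logL_i - 1e-6
            assert fit.lr2 == pytest.approx(2 * fit.lr)

    def test_identical_characters_strongly_coupled(self):
        tree = simulate_tree(SimConfig(n_taxa=24, depth=65.0, seed=8))
        rng = np.random.default_rng(8)
        tips = simulate_binary(tree, MkModel(0.02, 0.02), rng)
        fit = fit_pagel(tree, tips, dict(tips), seed=0, n_starts=2)
        assert fit.lr > 1.0

    def test_embedding_identity(self):
        rates = {"aG": 0.1, "aL": 0.2, "bG": 0.3, "bL": 0.4}
        emb = embed_independent(rates)
        assert np.allclose(dependent_rate_matrix(**emb),
                           independent_rate_matrix(**rates))


class TestSimulation:
    def test_all_rates_zero_keeps_root_state(self, balanced4):
        for nd in balanced4.preorder():
            if nd.parent is not None:
                nd.length = 5.0
        Q = np.zeros((4, 4))
        tipsA, tipsB = simulate_joint(balanced4, Q, seed=3,
                                      root_prior=[0, 0, 0, 1])
        assert set(tipsA.values()) == {1} and set(tipsB.values()) == {1}

    def test_fixed_seed_reproducible(self, balanced4):
        Q = independent_rate_matrix(0.5, 0.5, 0.5, 0.5)
        r1 = simulate_joint(balanced4, Q, seed=11)
        r2 = simulate_joint(balanced4, Q, seed=11)
        assert r1 == r2

    def test_long_branches_reach_stationary_frequencies(self):
        # symmetric high rates on long branches: each joint state ~ 1/4
        tree = simulate_tree(SimConfig(n_taxa=400, depth=500.0, seed=13))
        Q = independent_rate_matrix(0.5, 0.5, 0.5, 0.5)
        tipsA, tipsB = simulate_joint(tree, Q, seed=13)
        counts = np.zeros(4)
        for t in tipsA:
            counts[2 * tipsA[t] + tipsB[t]] += 1
        freqs = counts / counts.sum()
        assert np.allclose(freqs, 0.25, atol=0.08)


class TestMonteCarlo:
    def test_pvalue_bounded_and_monotone(self, small_sim):
        tree, matrix = small_sim
        fit = PagelCorrelation.from_matrix(tree, matrix,
                                           ("afterlife", "shamanism")).fit(
            n_starts=1, maxfun=60, seed=0)
        mc = fit.monte_carlo(n_sim=49, seed=1)
        assert 1.0 / 50 <= mc.pvalue <= 1.0
        # a larger observed LR can only shrink the p-value on the same null
        stronger = dataclasses.replace(mc, logL_d=mc.logL_d + 2.0)
        p_stronger = (1 + (mc.null_lr >= stronger.lr - 1e-9).sum()) / 50
        assert p_stronger <= mc.pvalue

    def test_zero_lr_gives_p_near_one(self, small_sim):
        tree, matrix = small_sim
        fit = PagelCorrelation.from_matrix(tree, matrix,
                                           ("afterlife", "shamanism")).fit(
            n_starts=1, maxfun=60, seed=0)
        null_fit = dataclasses.replace(fit, logL_d=fit.logL_i)  # LR -> 0
        mc = null_fit.monte_carlo(n_sim=29, seed=2)
        assert mc.pvalue >= 0.9

    def test_nsim_validated(self, small_sim):
        tree, matrix = small_sim
        fit = PagelCorrelation.from_matrix(tree, matrix,
                                           ("afterlife", "shamanism")).fit(
            n_starts=1, maxfun=60, seed=0)
        with pytest.raises(PagelError):
            fit.monte_carlo(n_sim=0)


class TestTransitionFlow:
    def test_flow_table_complete_and_nonnegative(self, small_sim):
        tree, matrix = small_sim
        fit = PagelCorrelation.from_matrix(tree, matrix,
                                           ("afterlife", "shamanism")).fit(
            n_starts=1, maxfun=60, seed=0)
        flow = fit.transition_flow()
        assert list(flow["rate"]) == list(DEP_RATE_NAMES)
        assert (flow["value"] >= 0).all()
        assert set(flow["change"]) == {"gain A", "loss A", "gain B", "loss B"}

    def test_dependent_gain_direction_recovered(self):
        # B gains 20x faster in the presence of A; the fitted dependent
        # model should reproduce that ordering of gain rates
        tree = simulate_tree(SimConfig(n_taxa=100, depth=65.0, seed=17))
        Q = dependent_gain_matrix(base=0.02, boost=20.0)
        tipsA, tipsB = simulate_joint(tree, Q, seed=17,
                                      root_prior=[1, 0, 0, 0])
        fit = fit_pagel(tree, tipsA, tipsB, seed=5, n_starts=2)
        assert fit.rates_d["q34"] > fit.rates_d["q12"]
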