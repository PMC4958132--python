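import numpy as np
import pytest

from cultrait import _ctmc
from cultrait.datasets import load_study_fixture
from cultrait.simulate import SimConfig, simulate_matrix, simulate_tree
from cultrait.tree import parse_newick


@pytest.fixture(scope="session", autouse=True)
def _compile_kernels():
    # trigger numba compilation once so per-test timings stay honest
    _ctmc.warm_up()


@pytest.fixture(scope="session")
def study_shallow():
    return load_study_fixture("shallow")


@pytest.fixture(scope="session")
def study_deep():
    return load_study_fixture("deep")


@pytest.fixture()
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture()
def small_sim():
    cfg = SimConfig(n_taxa=16, depth=65.0, seed=11)
    tree = simulate_tree(cfg)
    return tree, simulate_matrix(tree, cfg)


# ---------------------------------------------------------------------------
# Independent oracles (brute force / enumeration), used by several test files
# ---------------------------------------------------------------------------


def brute_force_loglik(tree, tips, Q, root_prior):
    """Sum over all internal-node state assignments of products of
    transition probabilities (scipy expm); exponential-time reference."""
    import itertools

    from scipy.linalg import expm

    k = Q.shape[0]
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    P = {id(nd): expm(np.asarray(Q) * nd.length) for nd in nodes
         if nd.parent is not None}
    total = 0.0
    leaf_choices = {}
    for nd in nodes:
        if nd.is_leaf:
            s = tips.get(nd.label, -1)
            leaf_choices[id(nd)] = [s] if s in range(k) else list(range(k))
    leaves = [nd for nd in nodes if nd.is_leaf]
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assign)}
        for leaf_assign in itertools.product(
                *[leaf_choices[id(lf)] for lf in leaves]):
            state = dict(amap)
            state.update({id(lf): s for lf, s in zip(leaves, leaf_assign)})
            p = root_prior[state[id(tree.root)]]
            for nd in nodes:
                if nd.parent is not None:
                    p *= P[id(nd)][state[id(nd.parent)], state[id(nd)]]
            total += p
    return np.log(total)


def brute_force_fitch(tree, states):
    """Exhaustive minimisation of state changes over all ancestral labelings
    (and over the states of missing-data leaves). Returns (min_steps,
    per-node optimal state sets keyed by id(node))."""
    import itertools

    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    leaves = [nd for nd in nodes if nd.is_leaf]
    leaf_choices = []
    for lf in leaves:
        s = states.get(lf.label, -1)
        leaf_choices.append([s] if s in (0, 1) else [0, 1])
    best = None
    opt_sets = {id(nd): set() for nd in nodes}
    records = []
    for assign in itertools.product((0, 1), repeat=len(internals)):
        for leaf_assign in itertools.product(*leaf_choices):
            state = {id(nd): s for nd, s in zip(internals, assign)}
            state.update({id(lf): s for lf, s in zip(leaves, leaf_assign)})
            steps = sum(
                1
                for nd in nodes
                if nd.parent is not None and state[id(nd)] != state[id(nd.parent)]
            )
            records.append((steps, state))
            if best is None or steps < best:
                best = steps
    for steps, state in records:
        if steps == best:
            for nd in nodes:
                opt_sets[id(nd)].add(state[id(nd)])
    return best, opt_sets


def random_binary_states(labels, rng, missing_frac=0.0):
    out = {}
    for lb in labels:
        if missing_frac and rng.random() < missing_frac:
            out[lb] = -1
        else:
            out[lb] = int(rng.integers(0, 2))
    return out
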