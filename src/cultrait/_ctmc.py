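"""Low-level continuous-time Markov chain kernels for pruning likelihoods.

The Felsenstein pruning recursion and a small-matrix exponential are
compiled with numba: the Monte Carlo null distribution of the correlated-
evolution test refits tens of thousands of models, so the per-evaluation
cost of the likelihood dominates the whole analysis.  The matrix
exponential uses scaling-and-squaring with a Taylor series, adequate to
~1e-13 for the 2x2 and 4x4 generators used here (tests compare it against
scipy.linalg.expm).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tree import Phylo, TreeError


class TreeArrays:
    """Postorder-indexed flat view of a tree for the numba kernels.

    Nodes are renumbered so every child precedes its parent and the root is
    last.  ``blen[i]`` is the branch above node ``i``; ``child_ptr`` /
    ``child_idx`` give each internal node's children in CSR form.
    """

    def __init__(self, tree: Phylo):
        nodes = list(tree.postorder())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.blen = np.zeros(n, dtype=np.float64)
        ptr = np.zeros(n + 1, dtype=np.int64)
        idx = []
        self.leaf_index = {}
        for i, nd in enumerate(nodes):
            if nd.parent is not None:
                if nd.length is None:
                    raise TreeError(
                        "likelihood computations need branch lengths on every edge"
                    )
                self.blen[i] = float(nd.length)
            for c in nd.children:
                idx.append(index[id(c)])
            ptr[i + 1] = len(idx)
            if nd.is_leaf:
                self.leaf_index[nd.label] = i
        self.child_ptr = ptr
        self.child_idx = np.asarray(idx, dtype=np.int64)
        self.nodes = nodes  # postorder Node objects, same indexing

    def tip_partials(self, states: dict, k: int) -> np.ndarray:
        """Per-node partial-likelihood seed array.

        ``states`` maps leaf label -> state index, with missing entries coded
        as -1 (or the label absent), which yields a flat partial of ones.
        """
        part = np.ones((self.n_nodes, k), dtype=np.float64)
        for label, i in self.leaf_index.items():
            s = states.get(label, -1)
            if s is None or s < 0:
                continue
            if s >= k:
                raise ValueError(f"state {s} out of range for {k}-state model")
            part[i, :] = 0.0
            part[i, s] = 1.0
        return part


@njit(cache=True)
def _matmul_inplace(A, B, C):
    """C = A @ B for small dense matrices (explicit loops: no BLAS overhead)."""
    k = A.shape[0]
    for i in range(k):
        for j in range(k):
            s = 0.0
            for l in range(k):
                s += A[i, l] * B[l, j]
            C[i, j] = s


@njit(cache=True)
def expm_small(Q, t):
    """exp(Q*t) for a small dense generator via scaling-and-squaring Taylor."""
    k = Q.shape[0]
    A = Q * t
    nrm = 0.0
    for i in range(k):
        row = 0.0
        for j in range(k):
            row += abs(A[i, j])
        if row > nrm:
            nrm = row
    s = 0
    while nrm > 0.5:
        nrm *= 0.5
        s += 1
    A = A / (2.0 ** s)
    P = np.eye(k) + A
    term = A.copy()
    tmp = np.empty((k, k))
    for m in range(2, 13):
        _matmul_inplace(term, A, tmp)
        for i in range(k):
            for j in range(k):
                term[i, j] = tmp[i, j] / m
                P[i, j] += term[i, j]
    for _ in range(s):
        _matmul_inplace(P, P, tmp)
        for i in range(k):
            for j in range(k):
                P[i, j] = tmp[i, j]
    return P


@njit(cache=True)
def branch_matrices(Q, blen):
    """Transition matrix for every branch; row 0 is unused (root)."""
    n = blen.shape[0]
    k = Q.shape[0]
    out = np.empty((n, k, k))
    for i in range(n):
        out[i] = expm_small(Q, blen[i])
    return out


@njit(cache=True)
def prune_loglik(child_ptr, child_idx, P, tip_part, root_prior):
    """Felsenstein pruning over a postorder-flattened tree.

    ``P[c]`` is the transition matrix on the branch above node ``c`` and
    ``tip_part`` the seed partials (ones for internal nodes).  Partials are
    rescaled per node to avoid underflow.
    """
    n, k = tip_part.shape
    part = tip_part.copy()
    logscale = 0.0
    for i in range(n):
        lo, hi = child_ptr[i], child_ptr[i + 1]
        if hi == lo:
            continue
        for s in range(k):
            part[i, s] = 1.0
        for ci in range(lo, hi):
            c = child_idx[ci]
            for s in range(k):
                acc = 0.0
                for s2 in range(k):
                    acc += P[c, s, s2] * part[c, s2]
                part[i, s] *= acc
        mx = part[i, 0]
        for s in range(1, k):
            if part[i, s] > mx:
                mx = part[i, s]
        if mx <= 0.0:
            return -np.inf
        for s in range(k):
            part[i, s] /= mx
        logscale += np.log(mx)
    root = n - 1
    like = 0.0
    for s in range(k):
        like += root_prior[s] * part[root, s]
    if like <= 0.0:
        return -np.inf
    return np.log(like) + logscale


@njit(cache=True)
def ctmc_loglik(child_ptr, child_idx, blen, Q, tip_part, root_prior):
    P = branch_matrices(Q, blen)
    return prune_loglik(child_ptr, child_idx, P, tip_part, root_prior)


@njit(cache=True)
def two_state_loglik(child_ptr, child_idx, blen, q01, q10, tip_part,
                     prior0, prior1):
    """Pruning for a two-state chain with the analytic P(t).

    P(same) = pi_same + (1 - pi_same) exp(-(q01+q10) t); exact, so this is
    the fast path for Mk1/asymmetric single-trait fits.
    """
    n = tip_part.shape[0]
    part = tip_part.copy()
    s = q01 + q10
    logscale = 0.0
    for i in range(n):
        lo, hi = child_ptr[i], child_ptr[i + 1]
        if hi == lo:
            continue
        p0 = 1.0
        p1 = 1.0
        for ci in range(lo, hi):
            c = child_idx[ci]
            e = np.exp(-s * blen[c])
            P00 = (q10 + q01 * e) / s
            P01 = (q01 * (1.0 - e)) / s
            P10 = (q10 * (1.0 - e)) / s
            P11 = (q01 + q10 * e) / s
            c0 = part[c, 0]
            c1 = part[c, 1]
            p0 *= P00 * c0 + P01 * c1
            p1 *= P10 * c0 + P11 * c1
        mx = p0 if p0 > p1 else p1
        if mx <= 0.0:
            return -np.inf
        part[i, 0] = p0 / mx
        part[i, 1] = p1 / mx
        logscale += np.log(mx)
    root = n - 1
    like = prior0 * part[root, 0] + prior1 * part[root, 1]
    if like <= 0.0:
        return -np.inf
    return np.log(like) + logscale


def loglik(arrays: TreeArrays, Q: np.ndarray, states: dict,
           root_prior: np.ndarray) -> float:
    """Log-likelihood of tip ``states`` under generator ``Q`` on a tree."""
    k = Q.shape[0]
    tip = arrays.tip_partials(states, k)
    return float(
        ctmc_loglik(arrays.child_ptr, arrays.child_idx, arrays.blen,
                    np.ascontiguousarray(Q, dtype=np.float64), tip,
                    np.ascontiguousarray(root_prior, dtype=np.float64))
    )


def partials_and_messages(arrays: TreeArrays, Q: np.ndarray, states: dict,
                          root_prior: np.ndarray):
    """Down partials, up messages and per-node marginals (numpy, unscaled-safe).

    Returns ``(marginals, loglik)`` where ``marginals[i]`` is the posterior
    state distribution of node ``i`` (postorder indexing).  Used for marginal
    ancestral state reconstruction; small trees, so plain numpy suffices.
    """
    k = Q.shape[0]
    n = arrays.n_nodes
    P = np.empty((n, k, k))
    for i in range(n):
        P[i] = expm_small(np.ascontiguousarray(Q, dtype=np.float64),
                          arrays.blen[i])
    down = arrays.tip_partials(states, k)
    scale = np.zeros(n)
    msg = np.empty((n, k))  # message from child c to its parent
    cp, ci = arrays.child_ptr, arrays.child_idx
    for i in range(n):
        kids = ci[cp[i]:cp[i + 1]]
        if len(kids):
            down[i] = 1.0
            for c in kids:
                msg[c] = P[c] @ down[c]
                down[i] *= msg[c]
            m = down[i].max()
            if m <= 0:
                raise FloatingPointError("zero partial likelihood")
            down[i] /= m
            scale[i] = np.log(m) + sum(scale[c] for c in kids)
        # leaves: message computed lazily when parent is processed
    root = n - 1
    like = float(root_prior @ down[root])
    ll = np.log(like) + scale[root]

    up = np.empty((n, k))
    up[root] = root_prior
    order = list(range(n - 1, -1, -1))  # reverse postorder = preorder
    for i in order:
        kids = ci[cp[i]:cp[i + 1]]
        for c in kids:
            others = np.ones(k)
            for d in kids:
                if d != c:
                    others *= msg[d]
            contrib = up[i] * others
            up[c] = contrib @ P[c]
            m = up[c].max()
            if m > 0:
                up[c] /= m
    marg = up * down
    tot = marg.sum(axis=1, keepdims=True)
    marg = marg / tot
    return marg, float(ll)


def fd_objective(fun, h: float = 1e-6):
    """Wrap a scalar objective as (value, forward-difference gradient).

    Batching the difference quotients into one call keeps the optimiser's
    per-iteration Python overhead flat, which matters when tens of
    thousands of small models are refitted for a Monte Carlo null.
    """

    def obj(x):
        f0 = fun(x)
        g = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            xp = x.copy()
            xp[i] += h
            g[i] = (fun(xp) - f0) / h
        return f0, g

    return obj


def warm_up():
    """Trigger numba compilation once (cheap 2-state call)."""
    cp = np.array([0, 0, 0, 2], dtype=np.int64)
    cidx = np.array([0, 1], dtype=np.int64)
    blen = np.array([0.0, 1.0, 1.0])
    Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
    tip = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    ctmc_loglik(cp, cidx, blen, Q, tip, np.array([0.5, 0.5]))
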