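"""Maximum-likelihood ancestral state reconstruction for binary characters.

The workhorse is the two-state Mk model of Lewis (2001): a continuous-time
Markov chain with a single rate ``q`` for both gains and losses (Mk1), or
separate forward/backward rates ``q01``/``q10`` (asymmetric).  Transition
probabilities have the closed form

    P(same state) = pi_same + (1 - pi_same) * exp(-(q01+q10) t)

which for Mk1 reduces to 1/2 + 1/2 exp(-2qt).  Ancestral states are the
marginal posterior state probabilities at each node ("proportional
likelihoods"), and a node is called significantly reconstructed when the
log-likelihood difference between the two states reaches a decision
threshold T (T = 2 corresponds to one state being e^2 ~ 7.4 times better
supported than the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from . import _ctmc
from .characters import MISSING, CharMatrix
from .tree import Phylo

RATE_FLOOR = 1e-8
RATE_CEIL = 1e3


class MkError(ValueError):
    pass


def support_ratio(threshold: float = 2.0) -> float:
    """Likelihood ratio implied by a log-likelihood decision threshold T."""
    return math.exp(threshold)


@dataclass(frozen=True)
class MkModel:
    """Two-state Markov model: equal-rates (Mk1) when ``q01 == q10``."""

    q01: float
    q10: float
    root_prior: str = "uniform"  # "uniform" | "stationary"

    def __post_init__(self):
        if self.q01 <= 0 or self.q10 <= 0:
            raise MkError("rates must be positive (floor 1e-8)")

    @classmethod
    def mk1(cls, q: float, root_prior: str = "uniform") -> "MkModel":
        return cls(q01=q, q10=q, root_prior=root_prior)

    @property
    def is_symmetric(self) -> bool:
        return self.q01 == self.q10

    def rate_matrix(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])

    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        return np.array([self.q10 / s, self.q01 / s])

    def root_prior_vector(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "uniform":
                return np.array([0.5, 0.5])
            if self.root_prior == "stationary":
                return self.stationary()
            raise MkError(f"unknown root prior {self.root_prior!r}")
        return np.asarray(self.root_prior, dtype=float)


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """Closed-form 2x2 transition probability matrix P(t) = exp(Qt)."""
    if t < 0:
        raise MkError("branch length must be non-negative")
    a, b = model.q01, model.q10
    s = a + b
    e = math.exp(-s * t)
    return np.array(
        [
            [(b + a * e) / s, (a * (1.0 - e)) / s],
            [(b * (1.0 - e)) / s, (a + b * e) / s],
        ]
    )


def _coerce_tips(tips) -> dict:
    out = {}
    for label, s in tips.items():
        if s in ("?", None, MISSING, -1):
            out[label] = -1
        elif s in (0, 1, "0", "1"):
            out[label] = int(s)
        else:
            raise MkError(f"tip {label!r}: state {s!r} is not binary")
    return out


def _check_coverage(tree: Phylo, tips: dict):
    missing = set(tree.leaf_labels) - set(tips)
    if missing:
        raise MkError(f"leaves missing from tip map: {sorted(missing)}")


def pruning_loglik(tree: Phylo, tips: dict, model: MkModel,
                   arrays: _ctmc.TreeArrays | None = None) -> float:
    """Felsenstein pruning log-likelihood of binary tip states."""
    tips = _coerce_tips(tips)
    _check_coverage(tree, tips)
    arrays = arrays or _ctmc.TreeArrays(tree)
    return _ctmc.loglik(arrays, model.rate_matrix(), tips,
                        model.root_prior_vector())


def fit_mk1(tree: Phylo, tips: dict, root_prior: str = "uniform",
            arrays: _ctmc.TreeArrays | None = None):
    """Fit the single rate of Mk1 by bounded 1-D optimisation on log q.

    Returns ``(model, loglik, converged)``.  A character with no observed
    variation drives the rate to the lower bound.
    """
    tips = _coerce_tips(tips)
    _check_coverage(tree, tips)
    arrays = arrays or _ctmc.TreeArrays(tree)
    tip_part = arrays.tip_partials(tips, 2)
    prior = np.array([0.5, 0.5])

    def nll(logq):
        q = math.exp(logq)
        return -_ctmc.two_state_loglik(arrays.child_ptr, arrays.child_idx,
                                       arrays.blen, q, q, tip_part,
                                       prior[0], prior[1])

    res = minimize_scalar(nll, bounds=(math.log(RATE_FLOOR), math.log(RATE_CEIL)),
                          method="bounded", options={"xatol": 1e-10})
    q = float(math.exp(res.x))
    model = MkModel.mk1(max(q, RATE_FLOOR), root_prior=root_prior)
    return model, -float(res.fun), bool(res.success)


def fit_asymmetric(tree: Phylo, tips: dict, root_prior: str = "stationary",
                   n_starts: int = 3, seed: int = 0,
                   arrays: _ctmc.TreeArrays | None = None):
    """Fit the 2-parameter asymmetric model (multi-start L-BFGS-B on log rates)."""
    tips = _coerce_tips(tips)
    _check_coverage(tree, tips)
    arrays = arrays or _ctmc.TreeArrays(tree)
    tip_part = arrays.tip_partials(tips, 2)

    def nll(x):
        a, b = np.exp(x)
        if root_prior == "stationary":
            p0, p1 = b / (a + b), a / (a + b)
        else:
            p0 = p1 = 0.5
        return -_ctmc.two_state_loglik(arrays.child_ptr, arrays.child_idx,
                                       arrays.blen, a, b, tip_part, p0, p1)

    rng = np.random.default_rng(seed)
    q0 = max(1.0 / max(arrays.blen.sum(), 1e-6), 10 * RATE_FLOOR)
    starts = [np.log([q0, q0])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(q0) + rng.normal(0.0, 1.5, size=2))
    best = None
    bounds = [(math.log(RATE_FLOOR), math.log(RATE_CEIL))] * 2
    obj = _ctmc.fd_objective(nll)
    for x0 in starts:
        res = minimize(obj, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    model = MkModel(q01=max(a, RATE_FLOOR), q10=max(b, RATE_FLOOR),
                    root_prior=root_prior)
    return model, -float(best.fun), bool(best.success)


def node_ids(tree: Phylo) -> dict:
    """Stable per-node identifiers: leaf labels, else N<k> in preorder."""
    ids, k = {}, 0
    for nd in tree.preorder():
        if nd.is_leaf:
            ids[id(nd)] = nd.label
        else:
            ids[id(nd)] = nd.label or f"N{k}"
            k += 1
    return ids


def marginal_asr(tree: Phylo, tips: dict, model: MkModel,
                 threshold: float = 2.0) -> pd.DataFrame:
    """Marginal (up-down) ancestral state probabilities at every node.

    Returns a table with one row per node: proportional likelihood of each
    state, the better state, and a significance flag set when the
    log-likelihood difference between states reaches ``threshold``.
    """
    tips = _coerce_tips(tips)
    _check_coverage(tree, tips)
    arrays = _ctmc.TreeArrays(tree)
    marg, ll = _ctmc.partials_and_messages(
        arrays, model.rate_matrix(), tips, model.root_prior_vector()
    )
    ids = node_ids(tree)
    rows = []
    for i, nd in enumerate(arrays.nodes):
        p0, p1 = marg[i]
        with np.errstate(divide="ignore"):
            delta = abs(np.log(max(p1, 1e-300)) - np.log(max(p0, 1e-300)))
        rows.append(
            {
                "node": ids[id(nd)],
                "is_leaf": nd.is_leaf,
                "age": nd.age,
                "p_absent": p0,
                "p_present": p1,
                "ml_state": int(p1 > p0),
                "log_ratio": delta,
                "significant": bool(delta >= threshold),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["loglik"] = ll
    df.attrs["threshold"] = threshold
    return df


@dataclass
class AsymmetryLRT:
    """Likelihood-ratio test of asymmetric (2-rate) vs Mk1 (1-rate)."""

    lr: float
    pvalue: float
    loglik_mk1: float
    loglik_asym: float
    mk1: MkModel
    asymmetric: MkModel

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def asymmetric_lrt(tree: Phylo, tips: dict, seed: int = 0,
                   arrays: _ctmc.TreeArrays | None = None) -> AsymmetryLRT:
    """Test whether separate gain and loss rates improve on Mk1.

    Both models use a uniform root prior so that Mk1 is nested exactly;
    LR = 2(lnL_asym - lnL_mk1) is referred to chi-square with 1 df.
    """
    arrays = arrays or _ctmc.TreeArrays(tree)
    mk1, ll1, _ = fit_mk1(tree, tips, arrays=arrays)
    asym, ll2, _ = fit_asymmetric(tree, tips, root_prior="uniform",
                                  seed=seed, arrays=arrays)
    if ll2 < ll1:  # asymmetric contains Mk1; keep the nested optimum
        asym, ll2 = MkModel(mk1.q01, mk1.q10, root_prior="uniform"), ll1
    lr = 2.0 * (ll2 - ll1)
    return AsymmetryLRT(lr=lr, pvalue=float(chi2.sf(max(lr, 0.0), df=1)),
                        loglik_mk1=ll1, loglik_asym=ll2, mk1=mk1,
                        asymmetric=asym)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class MkAncestralStates:
    """Ancestral state reconstruction model for one binary character.

    Parameters
    ----------
    tree : calibrated rooted tree (branch lengths in kya)
    tips : mapping leaf label -> {0, 1, '?'}
    model : "mk1" (single rate, uniform root prior) or "asymmetric"
    root_prior : override the default prior ("uniform" for Mk1,
        "stationary" for the asymmetric model)
    """

    def __init__(self, tree: Phylo, tips: dict, model: str = "mk1",
                 root_prior: str | None = None):
        if model not in ("mk1", "asymmetric"):
            raise MkError(f"unknown model {model!r}")
        self.tree = tree
        self.tips = _coerce_tips(tips)
        _check_coverage(tree, self.tips)
        self.model = model
        self.root_prior = root_prior or ("uniform" if model == "mk1" else "stationary")
        self._arrays = _ctmc.TreeArrays(tree)

    @classmethod
    def from_matrix(cls, tree: Phylo, matrix: CharMatrix, character: str,
                    **kwargs) -> "MkAncestralStates":
        return cls(tree, matrix.states_dict(character), **kwargs)

    def fit(self, threshold: float = 2.0, n_starts: int = 3,
            seed: int = 0) -> "MkAncestralStatesResults":
        if self.model == "mk1":
            mk, llf, conv = fit_mk1(self.tree, self.tips,
                                    root_prior=self.root_prior,
                                    arrays=self._arrays)
        else:
            mk, llf, conv = fit_asymmetric(self.tree, self.tips,
                                           root_prior=self.root_prior,
                                           n_starts=n_starts, seed=seed,
                                           arrays=self._arrays)
        table = marginal_asr(self.tree, self.tips, mk, threshold=threshold)
        return MkAncestralStatesResults(model=self, mk=mk, llf=llf,
                                        converged=conv, threshold=threshold,
                                        asr=table)


@dataclass
class MkAncestralStatesResults:
    """Fitted rates, log-likelihood and the per-node reconstruction table."""

    model: MkAncestralStates
    mk: MkModel
    llf: float
    converged: bool
    threshold: float
    asr: pd.DataFrame = field(repr=False)

    @property
    def rate(self) -> float:
        return self.mk.q01

    @property
    def rates(self) -> tuple:
        return (self.mk.q01, self.mk.q10)

    def node(self, node_id: str) -> pd.Series:
        hit = self.asr[self.asr["node"] == node_id]
        if hit.empty:
            raise MkError(f"no node {node_id!r} in the reconstruction table")
        return hit.iloc[0]

    def root(self) -> pd.Series:
        """The root row (id N0 in preorder naming, unless the root is labelled)."""
        ids = node_ids(self.model.tree)
        return self.node(ids[id(self.model.tree.root)])

    def ingroup_root(self, outgroup_label: str) -> pd.Series:
        """Reconstruction at the LCA of all non-outgroup leaves."""
        ingroup = [l for l in self.model.tree.leaf_labels if l != outgroup_label]
        node = self.model.tree.mrca(ingroup)
        ids = node_ids(self.model.tree)
        return self.node(ids[id(node)])

    def lrt_asymmetric(self, seed: int = 0) -> AsymmetryLRT:
        return asymmetric_lrt(self.model.tree, self.model.tips, seed=seed,
                              arrays=self.model._arrays)

    def summary(self) -> str:
        kind = "Mk1" if self.mk.is_symmetric else "asymmetric 2-rate"
        lines = [
            "Mk ancestral state reconstruction",
            "=" * 46,
            f"model:          {kind} (root prior: {self.mk.root_prior})",
            f"rate q01:       {self.mk.q01:.6g} /kya",
            f"rate q10:       {self.mk.q10:.6g} /kya",
            f"log-likelihood: {self.llf:.4f}",
            f"threshold T:    {self.threshold:g} "
            f"(support ratio {support_ratio(self.threshold):.3f})",
            "",
            "internal nodes:",
        ]
        sub = self.asr[~self.asr["is_leaf"]]
        for _, row in sub.iterrows():
            star = "*" if row["significant"] else " "
            lines.append(
                f"  {row['node']:<10} P(present)={row['p_present']:.4f}{star}"
            )
        return "\n".join(lines)
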