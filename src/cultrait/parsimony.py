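"""Parsimony ancestral reconstruction and homoplasy indices.

Step counts and most-parsimonious state sets are computed by dynamic
programming over unordered (Fitch) costs — exact on bifurcating and
multifurcating trees alike, with ``?`` treated as missing.  Homoplasy is
summarised by the consistency index CI = m/s and retention index
RI = (g - s)/(g - m), where ``m`` is the minimum conceivable number of
steps for the character (observed states minus one), ``s`` the realised
minimum on the tree, and ``g`` the maximum any tree could require (for a
binary character, the minority-state count).  Ensemble values sum m, s, g
over the parsimony-informative characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characters import MISSING, CharMatrix
from .mk import node_ids
from .tree import Phylo

INF = 10**9


class ParsimonyError(ValueError):
    pass


def _leaf_costs(states: dict, label: str, k: int = 2):
    if label not in states:
        raise ParsimonyError(f"leaf {label!r} missing from the character scores")
    s = states[label]
    cost = [INF] * k
    if s in (-1, MISSING, "?", None):
        return [0] * k
    s = int(s)
    if not 0 <= s < k:
        raise ParsimonyError(f"state {s} out of range (binary expected)")
    cost[s] = 0
    return cost


def fitch_counts(tree: Phylo, states: dict, k: int = 2):
    """Minimum step count and per-node most-parsimonious state sets.

    Returns ``(s, node_sets)`` where ``node_sets`` maps node id (leaf label
    or ``N<i>``) to the set of states occurring in at least one
    most-parsimonious labelling.
    """
    nodes = list(tree.postorder())
    down = {}
    for nd in nodes:
        if nd.is_leaf:
            down[id(nd)] = np.array(_leaf_costs(states, nd.label, k))
        else:
            tot = np.zeros(k, dtype=np.int64)
            for c in nd.children:
                dc = down[id(c)]
                # m_c(s) = min over child state s' of cost + (s != s')
                best = dc.min()
                tot += np.minimum(dc, best + 1)
            down[id(nd)] = tot

    root = tree.root
    s_min = int(down[id(root)].min())

    # up-pass: cost of the rest of the tree conditional on each node's state
    up = {id(root): np.zeros(k, dtype=np.int64)}
    for nd in tree.preorder():
        if nd.is_leaf:
            continue
        kids = nd.children
        msgs = []
        for c in kids:
            dc = down[id(c)]
            best = dc.min()
            msgs.append(np.minimum(dc, best + 1))
        for ci, c in enumerate(kids):
            others = up[id(nd)].copy()
            for cj, m in enumerate(msgs):
                if cj != ci:
                    others += m
            # up[c](s') = min over parent state s of others(s) + (s != s')
            best = others.min()
            up[id(c)] = np.minimum(others, best + 1)

    ids = node_ids(tree)
    node_sets = {}
    for nd in nodes:
        total = up[id(nd)] + down[id(nd)]
        node_sets[ids[id(nd)]] = {int(s) for s in range(k) if total[s] == s_min}
    return s_min, node_sets


@dataclass(frozen=True)
class FitchResult:
    """Parsimony reconstruction of one character."""

    character: str
    s: int  # realised minimum steps on the tree
    m: int  # minimum conceivable steps (observed states - 1)
    g: int  # maximum steps any tree could need (minority-state count)
    node_sets: dict = field(repr=False)

    @property
    def ci(self) -> float | None:
        return self.m / self.s if self.s > 0 else None

    @property
    def ri(self) -> float | None:
        return (self.g - self.s) / (self.g - self.m) if self.g > self.m else None

    def verdict(self, node_id: str) -> str:
        """Textual reading of the MPR set at a node."""
        st = self.node_sets[node_id]
        if st == {0}:
            return "absent"
        if st == {1}:
            return "present"
        return "equivocal"


def fitch_asr(tree: Phylo, matrix: CharMatrix, character: str,
              include_outgroup: bool = True) -> FitchResult:
    """Fitch parsimony reconstruction of a binary character on a tree."""
    if not matrix.is_binary(character):
        raise ParsimonyError(f"character {character!r} is not binary")
    states = matrix.states_dict(character, include_outgroup=include_outgroup)
    work_tree = tree
    if not include_outgroup and matrix.outgroup in tree.leaf_labels:
        work_tree = tree.prune_to([l for l in tree.leaf_labels
                                   if l != matrix.outgroup])
    scored = [s for l, s in states.items()
              if l in work_tree.leaf_labels and s != MISSING]
    n1 = sum(1 for s in scored if s == 1)
    n0 = len(scored) - n1
    m = 1 if (n0 and n1) else 0
    g = min(n0, n1)
    s, node_sets = fitch_counts(work_tree, states)
    return FitchResult(character=character, s=s, m=m, g=g, node_sets=node_sets)


def ci_ri(tree: Phylo, matrix: CharMatrix, include_outgroup: bool = True,
          exclude_constant: bool = True):
    """Per-character and ensemble consistency/retention indices.

    Characters that are constant (m = 0) are excluded from the ensemble
    sums when ``exclude_constant`` is set; RI is reported as missing for
    any character with g = m.
    """
    rows, results = [], {}
    sum_m = sum_s = sum_g = 0
    for ch in matrix.characters:
        res = fitch_asr(tree, matrix, ch, include_outgroup=include_outgroup)
        results[ch] = res
        if res.m > 0 or not exclude_constant:
            sum_m += res.m
            sum_s += res.s
            sum_g += res.g
        rows.append({"character": ch, "s": res.s, "m": res.m, "g": res.g,
                     "CI": res.ci, "RI": res.ri})
    table = pd.DataFrame(rows).set_index("character")
    ens_ci = sum_m / sum_s if sum_s > 0 else None
    ens_ri = (sum_g - sum_s) / (sum_g - sum_m) if sum_g > sum_m else None
    return table, ens_ci, ens_ri, results


class FitchParsimony:
    """Parsimony reconstruction model over a full character matrix.

    The hypothetical all-absent outgroup row (if the matrix carries one) is
    included by default, matching its use to root and polarise the
    characters; set ``include_outgroup=False`` for a sensitivity analysis
    on the ingroup alone.
    """

    def __init__(self, tree: Phylo, matrix: CharMatrix,
                 include_outgroup: bool = True,
                 exclude_constant: bool = True):
        self.tree = tree
        self.matrix = matrix
        self.include_outgroup = include_outgroup
        self.exclude_constant = exclude_constant

    def fit(self) -> "FitchParsimonyResults":
        table, ci, ri, results = ci_ri(
            self.tree, self.matrix,
            include_outgroup=self.include_outgroup,
            exclude_constant=self.exclude_constant,
        )
        return FitchParsimonyResults(model=self, table=table, ensemble_ci=ci,
                                     ensemble_ri=ri, characters=results)


@dataclass
class FitchParsimonyResults:
    model: FitchParsimony
    table: pd.DataFrame
    ensemble_ci: float | None
    ensemble_ri: float | None
    characters: dict = field(repr=False)

    def node_table(self) -> pd.DataFrame:
        """Long-format per-node MPR state sets for every character."""
        rows = []
        for ch, res in self.characters.items():
            for node, st in res.node_sets.items():
                rows.append({"node": node, "character": ch,
                             "states": "/".join(str(s) for s in sorted(st)),
                             "s": res.s, "m": res.m, "g": res.g,
                             "CI": res.ci, "RI": res.ri})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Fitch parsimony homoplasy summary", "=" * 46]
        for ch, row in self.table.iterrows():
            ci = f"{row['CI']:.3f}" if row["CI"] is not None and not pd.isna(row["CI"]) else "--"
            ri = f"{row['RI']:.3f}" if row["RI"] is not None and not pd.isna(row["RI"]) else "--"
            lines.append(f"  {ch:<26} s={int(row['s']):>3}  CI={ci}  RI={ri}")
        ci = f"{self.ensemble_ci:.3f}" if self.ensemble_ci is not None else "--"
        ri = f"{self.ensemble_ri:.3f}" if self.ensemble_ri is not None else "--"
        lines.append(f"  {'ensemble':<26} {'':>6}CI={ci}  RI={ri}")
        return "\n".join(lines)
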