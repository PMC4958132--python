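"""Matrix representation with parsimony (MRP) supertree construction.

Source trees are encoded Baum–Ragan style: every non-root internal node
contributes one binary character (descendants 1, the source's other taxa
0, taxa absent from that source ``?``).  Semi-rooted coding adds an
all-zero hypothetical outgroup that preserves the rooting of rooted
sources; for unrooted sources the outgroup is scored ``?`` and
complementary splits are collapsed to a single character.  A scaffold
(e.g. a linguistic classification tree) enters as ordinary characters
carrying a large weight so that its groupings behave as a topological
constraint.

The combined matrix is analysed by weighted Fitch parsimony with a
heuristic search: random-addition starting trees, subtree pruning and
regrafting (SPR, which subsumes NNI) hill-climbing with first-improvement
in a seeded random order, and parsimony-ratchet perturbation cycles.  The
returned best trees are summarised by a semi-strict (combinable component)
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characters import MISSING, DEFAULT_OUTGROUP
from .tree import Node, Phylo, TreeError

AMBIG = 2  # internal code for state set {0,1} during Fitch passes


class MRPError(ValueError):
    pass


class MRPMatrix:
    """Binary MRP character matrix with per-character weights and sources."""

    def __init__(self, taxa, data, weights, sources, outgroup=DEFAULT_OUTGROUP):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.int8)
        self.weights = np.asarray(weights, dtype=np.float64)
        self.sources = list(sources)
        self.outgroup = outgroup
        if self.data.shape != (len(self.taxa), len(self.weights)):
            raise MRPError("matrix shape does not match taxa/weights")
        if (self.weights < 1).any():
            raise MRPError("character weights must be >= 1")
        if len(set(self.taxa)) != len(self.taxa):
            raise MRPError("duplicate taxon labels")

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_characters(self):
        return len(self.weights)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.taxa,
                          columns=[f"{s}.{i}" for i, s in enumerate(self.sources)])
        return df.replace(MISSING, pd.NA)

    def __repr__(self):  # pragma: no cover
        return f"<MRPMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


def _tree_characters(tree: Phylo, rooted: bool):
    """Yield (leafset-of-1-side, source-taxa) for each encodable node/split."""
    all_leaves = frozenset(tree.leaf_labels)
    if len(all_leaves) != tree.n_leaves:
        raise MRPError("duplicate taxon labels within a source tree")
    seen = set()
    for nd in tree.internal_nodes():
        if nd is tree.root:
            continue
        clade = tree.leafset(nd)
        if len(clade) < 2 or clade == all_leaves:
            continue
        if rooted:
            key = clade
        else:
            # collapse complementary splits; orient the side holding the
            # lexicographically smallest taxon as state 1
            other = all_leaves - clade
            if not other:
                continue
            key = clade if min(clade) <= min(other) else other
        if key in seen:
            continue
        seen.add(key)
        yield key, all_leaves


def encode_mrp(sources, rooted=None, scaffold=None, scaffold_weight: float = 100.0,
               outgroup: str = DEFAULT_OUTGROUP) -> MRPMatrix:
    """Encode source trees (plus optional scaffold) as a weighted MRP matrix.

    Parameters
    ----------
    sources : list of Phylo source trees
    rooted : list of bool, one per source (default: all rooted)
    scaffold : a Phylo whose groupings are up-weighted, or an (characters,
        weight-ignored) MRPMatrix of grouping characters
    scaffold_weight : weight for scaffold characters (study value 100)
    """
    sources = list(sources)
    if not sources:
        raise MRPError("at least one source tree is required")
    if rooted is None:
        rooted = [True] * len(sources)
    if len(rooted) != len(sources):
        raise MRPError("rooted flags must match the number of sources")
    if scaffold_weight < 1:
        raise MRPError("scaffold_weight must be >= 1")

    taxa = set()
    for t in sources:
        taxa |= set(t.leaf_labels)
    scaffold_chars = []
    if isinstance(scaffold, Phylo):
        taxa |= set(scaffold.leaf_labels)
    elif isinstance(scaffold, MRPMatrix):
        taxa |= set(t for t in scaffold.taxa if t != scaffold.outgroup)
    if outgroup in taxa:
        raise MRPError(f"outgroup label {outgroup!r} collides with a source taxon")
    taxa = sorted(taxa)
    tidx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa) + 1  # + outgroup row (last)

    cols, weights, col_sources = [], [], []

    def add_column(ones, zeros, out_state, weight, source_id):
        col = np.full(n, MISSING, dtype=np.int8)
        for t in ones:
            col[tidx[t]] = 1
        for t in zeros:
            col[tidx[t]] = 0
        col[-1] = out_state
        cols.append(col)
        weights.append(weight)
        col_sources.append(source_id)

    for k, (tree, is_rooted) in enumerate(zip(sources, rooted)):
        for clade, source_taxa in _tree_characters(tree, is_rooted):
            add_column(clade, source_taxa - clade,
                       0 if is_rooted else MISSING, 1.0, f"source{k}")

    if isinstance(scaffold, Phylo):
        for clade, source_taxa in _tree_characters(scaffold, True):
            add_column(clade, source_taxa - clade, 0, scaffold_weight, "scaffold")
    elif isinstance(scaffold, MRPMatrix):
        for j in range(scaffold.n_characters):
            col = np.full(n, MISSING, dtype=np.int8)
            for t, s in zip(scaffold.taxa, scaffold.data[:, j]):
                if t == scaffold.outgroup:
                    col[-1] = s
                elif s != MISSING:
                    col[tidx[t]] = s
            if col[-1] == MISSING:
                col[-1] = 0
            cols.append(col)
            weights.append(scaffold_weight)
            col_sources.append("scaffold")
    elif scaffold is not None:
        raise MRPError("scaffold must be a Phylo or an MRPMatrix")

    if not cols:
        raise MRPError("no informative characters could be encoded")
    return MRPMatrix(taxa + [outgroup], np.column_stack(cols), weights,
                     col_sources, outgroup=outgroup)


# ---------------------------------------------------------------------------
# Weighted Fitch length
# ---------------------------------------------------------------------------


def _leaf_codes(matrix: MRPMatrix) -> dict:
    """Per-taxon state-set codes (0, 1, or AMBIG for '?') per character."""
    codes = {}
    for i, t in enumerate(matrix.taxa):
        row = matrix.data[i].astype(np.int8).copy()
        row[row == MISSING] = AMBIG
        codes[t] = row
    return codes


def _fitch_steps_codes(tree: Phylo, codes: dict, n_chars: int) -> np.ndarray:
    """Per-character minimum steps for binary characters with missing data.

    Uses the exact multifurcation rule: at each internal node, with n0
    children resolved to {0} and n1 to {1}, min(n0, n1) changes are added
    and the node becomes {0}, {1} or {0,1} by majority.
    """
    steps = np.zeros(n_chars, dtype=np.float64)
    default = np.full(n_chars, AMBIG, dtype=np.int8)
    node_code = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            node_code[id(nd)] = codes.get(nd.label, default)
            continue
        kid_codes = np.stack([node_code.pop(id(c)) for c in nd.children])
        n0 = (kid_codes == 0).sum(axis=0)
        n1 = (kid_codes == 1).sum(axis=0)
        steps += np.minimum(n0, n1)
        node_code[id(nd)] = np.where(
            n0 > n1, 0, np.where(n1 > n0, 1, AMBIG)
        ).astype(np.int8)
    return steps


def fitch_length(tree: Phylo, matrix: MRPMatrix) -> float:
    """Weighted Fitch tree length: sum of weight x minimum state changes."""
    extra = set(matrix.taxa) - set(tree.leaf_labels)
    if extra:
        raise MRPError(f"matrix taxa missing from tree: {sorted(extra)}")
    steps = _fitch_steps_codes(tree, _leaf_codes(matrix), matrix.n_characters)
    return float(steps @ matrix.weights)


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------


def _binary_tree_from_order(taxa_order, matrix, weights, rng):
    """Stepwise addition: insert taxa in the given order at the best edge."""
    codes = _leaf_codes(matrix)

    def leaf(t):
        return Node(label=t)

    root = Node()
    root.add_child(leaf(taxa_order[0]))
    root.add_child(leaf(taxa_order[1]))
    tree = Phylo(root)
    for t in taxa_order[2:]:
        best, best_score = None, np.inf
        spots = [nd for nd in tree.preorder() if nd is not tree.root]
        rng.shuffle(spots)
        for target in spots:
            par = target.parent
            newnode = Node(label=None)
            i = par.children.index(target)
            par.children[i] = newnode
            newnode.parent = par
            newnode.add_child(target)
            newnode.add_child(leaf(t))
            score = _weighted_steps(tree, codes, weights)
            if score < best_score:
                best, best_score = target, score
            # undo
            par.children[i] = target
            target.parent = par
        # commit the best insertion
        par = best.parent
        newnode = Node(label=None)
        i = par.children.index(best)
        par.children[i] = newnode
        newnode.parent = par
        newnode.add_child(best)
        newnode.add_child(leaf(t))
    return tree


def _weighted_steps(tree, codes, weights):
    steps = _fitch_steps_codes(tree, codes, len(weights))
    return float(steps @ weights)


def _subtree_node_ids(node):
    out, stack = set(), [node]
    while stack:
        nd = stack.pop()
        out.add(id(nd))
        stack.extend(nd.children)
    return out


def _spr_neighbors(tree: Phylo, rng):
    """Yield SPR rearrangements of a rooted binary tree, in random order.

    Each neighbour is produced by detaching a non-root subtree and
    regrafting it onto another edge; the score is rooting-invariant, so
    rooted SPR explores the unrooted neighbourhood (and subsumes NNI).
    """
    nodes = [nd for nd in tree.preorder()]
    prune_candidates = [nd for nd in nodes if nd.parent is not None]
    rng.shuffle(prune_candidates)
    for prune in prune_candidates:
        par = prune.parent
        if par is tree.root and len(tree.root.children) <= 2:
            siblings = [c for c in par.children if c is not prune]
            if len(siblings) == 1 and siblings[0].is_leaf and prune.is_leaf:
                continue
        forbidden = _subtree_node_ids(prune)
        forbidden.add(id(par))
        targets = [nd for nd in nodes
                   if id(nd) not in forbidden and nd.parent is not None]
        rng.shuffle(targets)
        for target in targets:
            yield prune, target


def _apply_spr(tree: Phylo, prune: Node, target: Node) -> Phylo:
    """Copy the tree, detach ``prune``'s subtree and regraft above ``target``."""
    mapping = {}

    def rec(nd):
        new = Node(nd.label, nd.length, nd.age)
        mapping[id(nd)] = new
        for c in nd.children:
            new.add_child(rec(c))
        return new

    new_root = rec(tree.root)
    p = mapping[id(prune)]
    t = mapping[id(target)]
    par = p.parent
    par.children.remove(p)
    p.parent = None
    # collapse a now-unary parent
    if len(par.children) == 1:
        only = par.children[0]
        gp = par.parent
        if gp is None:
            only.parent = None
            new_root = only
        else:
            i = gp.children.index(par)
            gp.children[i] = only
            only.parent = gp
    if t.parent is None:  # target became root after collapse: graft above root
        fresh = Node()
        fresh.add_child(t)
        fresh.add_child(p)
        new_root = fresh
    else:
        tpar = t.parent
        i = tpar.children.index(t)
        fresh = Node()
        tpar.children[i] = fresh
        fresh.parent = tpar
        fresh.add_child(t)
        fresh.add_child(p)
    return Phylo(new_root)


def _hill_climb(tree, codes, weights, rng, max_rounds=50):
    score = _weighted_steps(tree, codes, weights)
    improved = True
    rounds = 0
    while improved and rounds < max_rounds:
        improved = False
        rounds += 1
        for prune, target in _spr_neighbors(tree, rng):
            cand = _apply_spr(tree, prune, target)
            s = _weighted_steps(cand, codes, weights)
            if s < score - 1e-9:
                tree, score = cand, s
                improved = True
                break  # first improvement, restart neighbourhood
    return tree, score


def _splits_key(tree: Phylo) -> frozenset:
    """Canonical unrooted-topology key: the set of splits, each split
    represented by the side not containing the reference (min) taxon."""
    leaves = frozenset(tree.leaf_labels)
    ref = min(leaves)
    key = set()
    for nd in tree.internal_nodes():
        clade = tree.leafset(nd)
        if len(clade) < 2 or clade == leaves:
            continue
        side = clade if ref not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            key.add(side)
    return frozenset(key)


def root_at(tree: Phylo, outgroup: str) -> Phylo:
    """Reroot (topology only) so the outgroup leaf is a child of the root."""
    og = tree.find_leaf(outgroup)
    if og.parent is tree.root and len(tree.root.children) == 2:
        return tree.copy()

    def copy_subtree(nd):
        new = Node(nd.label)
        for c in nd.children:
            new.add_child(copy_subtree(c))
        return new

    def rehang(nd, come_from):
        """Copy of the tree as seen from ``nd`` arriving via ``come_from``."""
        new = Node(nd.label)
        for c in nd.children:
            if c is not come_from:
                new.add_child(copy_subtree(c))
        if nd.parent is not None and nd.parent is not come_from:
            new.add_child(rehang(nd.parent, nd))
        return new

    new_root = Node()
    new_root.add_child(Node(og.label))
    new_root.add_child(rehang(og.parent, og))
    return Phylo(_collapse_unary(new_root))


def _collapse_unary(root: Node) -> Node:
    def rec(nd):
        nd.children = [rec(c) for c in nd.children]
        for c in nd.children:
            c.parent = nd
        if len(nd.children) == 1 and nd.label is None:
            child = nd.children[0]
            child.parent = nd.parent
            return child
        return nd

    root = rec(root)
    root.parent = None
    return root


def parsimony_search(matrix: MRPMatrix, n_addition_replicates: int = 10,
                     seed: int = 0, ratchet_cycles: int = 2,
                     keep_max: int = 50):
    """Heuristic weighted-parsimony search over binary (unrooted) topologies.

    Random-addition starting trees, SPR hill-climbing with first
    improvement in a seeded random visit order, and parsimony-ratchet
    cycles (a random ~25% of characters are temporarily up-weighted x3,
    the tree re-optimised, weights restored, and re-optimised again).
    Returns ``(best_trees, best_score, log)``: all distinct best
    topologies (rooted at the outgroup), the best weighted length, and a
    per-replicate score log.
    """
    if n_addition_replicates < 1:
        raise MRPError("n_addition_replicates must be >= 1")
    if matrix.n_taxa < 4:
        raise MRPError("need at least 4 taxa to search")
    rng = np.random.default_rng(seed)
    codes = _leaf_codes(matrix)
    weights = matrix.weights
    best_score = np.inf
    best = {}
    log = []
    for rep in range(n_addition_replicates):
        order = list(matrix.taxa)
        rng.shuffle(order)
        tree = _binary_tree_from_order(order, matrix, weights, rng)
        tree, score = _hill_climb(tree, codes, weights, rng)
        for _ in range(ratchet_cycles):
            boosted = weights.copy()
            mask = rng.random(len(weights)) < 0.25
            boosted[mask] *= 3.0
            perturbed, _ = _hill_climb(tree, codes, boosted, rng, max_rounds=10)
            cand, cand_score = _hill_climb(perturbed, codes, weights, rng)
            if cand_score < score - 1e-9:
                tree, score = cand, cand_score
        log.append({"replicate": rep, "score": score})
        if score < best_score - 1e-9:
            best_score = score
            best = {_splits_key(tree): tree}
        elif abs(score - best_score) <= 1e-9 and len(best) < keep_max:
            best.setdefault(_splits_key(tree), tree)
    rooted = [root_at(t, matrix.outgroup) for t in best.values()]
    return rooted, float(best_score), pd.DataFrame(log)


def enumerate_unrooted_topologies(taxa):
    """All distinct unrooted binary topologies, as rooted Phylo objects.

    Generated by recursive stepwise insertion ((2n-5)!! trees); intended
    for exhaustive searches on small taxon sets.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise MRPError("need at least 3 taxa")

    def clone(nd):
        new = Node(nd.label)
        for c in nd.children:
            new.add_child(clone(c))
        return new

    base = Node()
    for t in taxa[:3]:
        base.add_child(Node(t))
    trees = [base]
    for t in taxa[3:]:
        nxt = []
        for tr in trees:
            edges = [nd for nd in _preorder_nodes(tr) if nd.parent is not None]
            for k in range(len(edges)):
                new_tr = clone(tr)
                target = [nd for nd in _preorder_nodes(new_tr)
                          if nd.parent is not None][k]
                par = target.parent
                i = par.children.index(target)
                mid = Node()
                par.children[i] = mid
                mid.parent = par
                mid.add_child(target)
                mid.add_child(Node(t))
                nxt.append(new_tr)
        trees = nxt
    return [Phylo(tr) for tr in trees]


def _preorder_nodes(root: Node):
    out, stack = [], [root]
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(reversed(nd.children))
    return out


# ---------------------------------------------------------------------------
# Consensus and pruning
# ---------------------------------------------------------------------------


def semi_strict_consensus(trees) -> Phylo:
    """Combinable-component consensus of rooted trees on one leaf set.

    Retains every clade present in at least one input tree and
    contradicted (overlapping, neither nested) by none.
    """
    trees = list(trees)
    if not trees:
        raise MRPError("no trees given")
    leafset = frozenset(trees[0].leaf_labels)
    clade_sets = []
    for t in trees:
        if frozenset(t.leaf_labels) != leafset:
            raise MRPError("consensus inputs must share one leaf set")
        clade_sets.append({t.leafset(nd) for nd in t.internal_nodes()
                           if 1 < len(t.leafset(nd)) < len(leafset)})
    candidates = set().union(*clade_sets)
    kept = []
    for clade in candidates:
        ok = True
        for cs in clade_sets:
            for other in cs:
                inter = clade & other
                if inter and not (clade <= other or other <= clade):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(clade)
    return _tree_from_clades(leafset, kept)


def _tree_from_clades(leafset, clades) -> Phylo:
    clades = sorted(set(clades), key=len, reverse=True)
    root = Node()
    node_of = {frozenset(leafset): root}
    order = [frozenset(leafset)] + clades
    for clade in clades:
        parent = min((c for c in order if clade < c), key=len)
        nd = Node()
        node_of[parent].add_child(nd)
        node_of[clade] = nd
    for leaf in sorted(leafset):
        parent = min((c for c in order if leaf in c), key=len)
        node_of[parent].add_child(Node(leaf))
    return Phylo(root)


def prune_supertree(tree: Phylo, keep) -> Phylo:
    """Induced subtree on ``keep`` (degree-2 nodes collapsed, lengths summed)."""
    return tree.prune_to(keep)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class MRPSupertree:
    """MRP supertree model over a set of source trees.

    Parameters mirror the encoding: per-source rooted flags, an optional
    up-weighted scaffold, and the hypothetical outgroup label.
    """

    def __init__(self, sources, rooted=None, scaffold=None,
                 scaffold_weight: float = 100.0, outgroup: str = DEFAULT_OUTGROUP):
        self.matrix = encode_mrp(sources, rooted=rooted, scaffold=scaffold,
                                 scaffold_weight=scaffold_weight,
                                 outgroup=outgroup)
        self.outgroup = outgroup

    def fit(self, n_replicates: int = 10, seed: int = 0,
            ratchet_cycles: int = 2) -> "MRPSupertreeResults":
        trees, score, log = parsimony_search(
            self.matrix, n_addition_replicates=n_replicates, seed=seed,
            ratchet_cycles=ratchet_cycles)
        consensus = semi_strict_consensus(trees) if len(trees) > 1 else trees[0]
        return MRPSupertreeResults(model=self, best_trees=trees,
                                   best_score=score, consensus=consensus,
                                   log=log)


@dataclass
class MRPSupertreeResults:
    model: MRPSupertree
    best_trees: list
    best_score: float
    consensus: Phylo
    log: pd.DataFrame = field(repr=False)

    def consensus_pruned(self, keep) -> Phylo:
        return prune_supertree(self.consensus, keep)

    def summary(self) -> str:
        m = self.model.matrix
        return "\n".join([
            "MRP supertree search",
            "=" * 46,
            f"taxa:              {m.n_taxa} (incl. outgroup {m.outgroup!r})",
            f"characters:        {m.n_characters} "
            f"({sum(s == 'scaffold' for s in m.sources)} scaffold)",
            f"best weighted len: {self.best_score:g}",
            f"best topologies:   {len(self.best_trees)}",
            f"replicates:        {len(self.log)}",
        ])
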