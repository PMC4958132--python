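"""Rooted phylogenies with node ages, Newick/NEXUS I/O, and time calibration.

Trees are rooted, may contain polytomies, and carry branch lengths in the
same unit as node ages (kya throughout this package).  Ages increase
root-ward: extant leaves sit at age 0 and ``age(parent) - age(child)``
equals the connecting branch length on a calibrated tree.

Calibration follows the minimum-node-age approach used for supertrees that
lack molecular branch lengths: a table of clade-wise minimum ages is
enforced (propagating root-ward so no parent is younger than a child) and
the remaining, unconstrained nodes are interpolated between the nearest
fixed ancestor and the oldest fixed descendant ("arbitrary
ultrametricization").  The default interpolation spaces the nodes of each
intervening chain evenly; an alternative spreads them proportionally to the
original branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Malformed tree, label mismatch, or violated age invariant."""


class NewickParseError(TreeError):
    """Syntactically invalid Newick/NEXUS input."""


class CalibrationError(TreeError):
    """Unsatisfiable or non-monophyletic age constraint."""


class Node:
    """A node in a rooted tree.

    ``length`` is the branch to the parent (None for an uncalibrated root),
    ``age`` the node's height above the extant leaves (kya), and ``fixed``
    marks ages pinned by calibration constraints.
    """

    __slots__ = ("label", "length", "age", "parent", "children", "fixed")

    def __init__(self, label=None, length=None, age=None):
        self.label = label
        self.length = length
        self.age = age
        self.parent = None
        self.children = []
        self.fixed = False

    @property
    def is_leaf(self):
        return not self.children

    def add_child(self, node):
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} age={self.age} len={self.length}>"


class Phylo:
    """A rooted phylogeny (possibly multifurcating) with unique leaf labels."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self):
        labels = [lf.label for lf in self.leaves()]
        if any(lb is None for lb in labels):
            raise TreeError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            dup = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        for nd in self.postorder():
            if nd.length is not None and nd.length < -1e-12:
                raise TreeError(f"negative branch length at {nd.label!r}")

    def check_ages(self, tol: float = 1e-9):
        """Raise unless present ages are consistent with lengths and leaves at 0."""
        for nd in self.preorder():
            if nd.age is None:
                continue
            if nd.is_leaf and abs(nd.age) > tol:
                raise TreeError(f"extant leaf {nd.label!r} has age {nd.age}")
            if nd.parent is not None and nd.parent.age is not None:
                if nd.parent.age < nd.age - tol:
                    raise TreeError(
                        f"parent younger than child near {nd.label or 'internal'!r}"
                    )
                if nd.length is not None and abs(
                    (nd.parent.age - nd.age) - nd.length
                ) > max(tol, 1e-9 * max(1.0, abs(nd.length))):
                    raise TreeError("branch length inconsistent with node ages")

    # -- traversal ------------------------------------------------------

    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self):
        return [nd for nd in self.preorder() if nd.is_leaf]

    @property
    def leaf_labels(self):
        return [lf.label for lf in self.leaves()]

    @property
    def n_leaves(self):
        return len(self.leaves())

    def internal_nodes(self, exclude_root: bool = False):
        return [
            nd
            for nd in self.preorder()
            if not nd.is_leaf and not (exclude_root and nd is self.root)
        ]

    def find_leaf(self, label):
        for lf in self.leaves():
            if lf.label == label:
                return lf
        raise TreeError(f"no leaf labelled {label!r}")

    def leafset(self, node: Node) -> frozenset:
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd.label)
            else:
                stack.extend(nd.children)
        return frozenset(out)

    def mrca(self, labels) -> Node:
        want = set(labels)
        missing = want - set(self.leaf_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        node = self.find_leaf(next(iter(want)))
        while not want <= self.leafset(node):
            node = node.parent
        return node

    # -- ages and lengths ----------------------------------------------

    def set_ages_from_lengths(self, tol: float = 1e-6):
        """Derive node ages from branch lengths; requires an ultrametric tree."""
        depth = {self.root: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            if nd.length is None:
                raise TreeError("branch lengths required to derive ages")
            depth[nd] = depth[nd.parent] + nd.length
        total = max(depth[lf] for lf in self.leaves())
        for lf in self.leaves():
            if abs(depth[lf] - total) > tol * max(1.0, total):
                raise TreeError("tree is not ultrametric; cannot assign leaf age 0")
        for nd in self.preorder():
            nd.age = total - depth[nd]
        for lf in self.leaves():
            lf.age = 0.0
        return self

    def set_lengths_from_ages(self):
        for nd in self.preorder():
            if nd.age is None:
                raise TreeError("all nodes need ages to derive branch lengths")
            if nd.parent is not None:
                ln = nd.parent.age - nd.age
                if ln < -1e-9:
                    raise TreeError("parent younger than child")
                nd.length = max(ln, 0.0)
        return self

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depth = {self.root: 0.0}
        leaf_depths = []
        for nd in self.preorder():
            if nd is self.root:
                continue
            if nd.length is None:
                return False
            depth[nd] = depth[nd.parent] + nd.length
            if nd.is_leaf:
                leaf_depths.append(depth[nd])
        return max(leaf_depths) - min(leaf_depths) <= tol * max(1.0, max(leaf_depths))

    @property
    def depth(self) -> float:
        """Maximum root-to-leaf path length."""
        best = 0.0
        depth = {self.root: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            depth[nd] = depth[nd.parent] + (nd.length or 0.0)
            if nd.is_leaf:
                best = max(best, depth[nd])
        return best

    def copy(self) -> "Phylo":
        def rec(nd):
            new = Node(nd.label, nd.length, nd.age)
            new.fixed = nd.fixed
            for c in nd.children:
                new.add_child(rec(c))
            return new

        return Phylo(rec(self.root))

    def prune_to(self, keep) -> "Phylo":
        """Induced subtree on ``keep``; unary chains collapsed, lengths summed."""
        keep = set(keep)
        extra = keep - set(self.leaf_labels)
        if extra:
            raise TreeError(f"labels not in tree: {sorted(extra)}")

        def rec(nd):
            if nd.is_leaf:
                if nd.label in keep:
                    return Node(nd.label, nd.length, nd.age)
                return None
            kids = [k for k in (rec(c) for c in nd.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if child.length is not None and nd.length is not None:
                    child.length += nd.length
                elif nd.length is not None:
                    child.length = nd.length
                return child
            new = Node(nd.label, nd.length, nd.age)
            for k in kids:
                new.add_child(k)
            return new

        root = rec(self.root)
        if root is None:
            raise TreeError("pruning removed every leaf")
        root.parent = None
        return Phylo(root)

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylo":
        return parse_newick(text)

    def to_newick(self, include_lengths: bool = True) -> str:
        return write_newick(self, include_lengths=include_lengths)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def rec(nd, dnode):
            dnode.edge.length = nd.length
            if nd.is_leaf:
                dnode.taxon = tns.require_taxon(label=nd.label)
            else:
                if nd.label:
                    dnode.label = nd.label
                for c in nd.children:
                    rec(c, dnode.new_child())

        rec(self.root, dtree.seed_node)
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylo":
        def rec(dnode):
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            nd = Node(label=label, length=dnode.edge.length)
            for dc in dnode.child_nodes():
                nd.add_child(rec(dc))
            return nd

        return cls(rec(dtree.seed_node))

    def __repr__(self):  # pragma: no cover
        return f"<Phylo {self.n_leaves} leaves, depth={self.depth:.3g}>"


def parse_newick(text: str) -> Phylo:
    """Parse a single Newick tree (branch lengths optional)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"invalid Newick: {exc}") from None
    tree = Phylo.from_dendropy(dtree)
    if tree.root.is_leaf and not tree.root.children:
        raise NewickParseError("input encodes no tree")
    return tree


def write_newick(tree: Phylo, include_lengths: bool = True) -> str:
    def fmt(x: float) -> str:
        s = repr(float(x))
        return s[:-2] if s.endswith(".0") else s

    def rec(nd):
        if nd.is_leaf:
            base = _quote(nd.label)
        else:
            base = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if nd.label:
                base += _quote(nd.label)
        if include_lengths and nd.length is not None:
            base += f":{fmt(nd.length)}"
        return base

    return rec(tree.root) + ";"


def _quote(label: str) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_trees(path, schema: str = "newick") -> list:
    """Read all trees from a Newick file or a NEXUS TREES block."""
    tl = dendropy.TreeList.get(
        path=str(path),
        schema=schema,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return [Phylo.from_dendropy(t) for t in tl]


def write_trees(trees, path, schema: str = "newick"):
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    tl.write(path=str(path), schema=schema, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Time calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeConstraint:
    """Minimum age (kya) for the most recent common ancestor of ``leaves``."""

    clade_id: str
    leaves: frozenset
    min_age: float

    def __post_init__(self):
        if self.min_age <= 0:
            raise CalibrationError(f"constraint {self.clade_id}: age must be > 0")
        if len(self.leaves) < 1:
            raise CalibrationError(f"constraint {self.clade_id}: empty clade")


@dataclass
class AgeConstraintSet:
    """A named set of minimum node-age constraints (e.g. deep vs shallow dates)."""

    constraints: list = field(default_factory=list)
    date_set: str = "default"

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self):
        return len(self.constraints)

    @classmethod
    def from_tsv(cls, path, date_set: str) -> "AgeConstraintSet":
        """Read constraints from a TSV with columns
        clade_id, date_set, min_age_kya, leaf_set (comma-separated labels)."""
        constraints = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for col in ("clade_id", "date_set", "min_age_kya", "leaf_set"):
                if col not in idx:
                    raise CalibrationError(f"constraint table lacks column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[idx["date_set"]] != date_set:
                    continue
                constraints.append(
                    AgeConstraint(
                        clade_id=parts[idx["clade_id"]],
                        leaves=frozenset(parts[idx["leaf_set"]].split(",")),
                        min_age=float(parts[idx["min_age_kya"]]),
                    )
                )
        if not constraints:
            raise CalibrationError(f"no constraints for date set {date_set!r}")
        return cls(constraints=constraints, date_set=date_set)


def enforce_min_node_ages(tree: Phylo, constraints: AgeConstraintSet) -> Phylo:
    """Pin each constrained clade's age to at least its minimum.

    Returns a copy in which every constrained MRCA carries ``age >= min_age``
    and is flagged ``fixed``; ages propagate root-ward so no parent is younger
    than a fixed child (a parent raised this way becomes fixed too).  A clade
    specifier whose MRCA contains extra leaves is rejected as non-monophyletic.
    """
    out = tree.copy()
    for lf in out.leaves():
        lf.age = 0.0
    for con in constraints:
        node = out.mrca(con.leaves)
        observed = out.leafset(node)
        if len(con.leaves) > 1 and observed != con.leaves:
            extra = sorted(observed - con.leaves)
            raise CalibrationError(
                f"constraint {con.clade_id!r} is not monophyletic: "
                f"MRCA also contains {extra}"
            )
        if node.is_leaf:
            raise CalibrationError(
                f"constraint {con.clade_id!r} resolves to an extant leaf"
            )
        node.age = max(node.age or 0.0, con.min_age)
        node.fixed = True
    # root-ward propagation
    for nd in out.postorder():
        if nd.age is None or nd.parent is None:
            continue
        par = nd.parent
        if par.age is not None and par.age < nd.age:
            par.age = nd.age
            par.fixed = True
        elif par.age is None and nd.fixed:
            pass  # left to ultrametricize; it interpolates above fixed children
    return out


def ultrametricize(tree: Phylo, mode: str = "even", root_age: float | None = None) -> Phylo:
    """Assign ages to unconstrained internal nodes and rebuild branch lengths.

    Leaves sit at age 0 and ``fixed`` nodes keep their ages.  Every other
    internal node is interpolated strictly between its nearest fixed ancestor
    and its oldest fixed (or leaf) descendant.  ``mode="even"`` spaces the
    nodes of the intervening chain evenly; ``mode="proportional"`` spaces
    them proportionally to the original branch lengths.  The root must be
    fixed, already aged, or supplied via ``root_age``.
    """
    if mode not in ("even", "proportional"):
        raise ValueError(f"unknown mode {mode!r}")
    out = tree.copy()
    for lf in out.leaves():
        lf.age = 0.0
        lf.fixed = True
    if root_age is not None:
        if out.root.age is not None and out.root.age > root_age:
            raise CalibrationError("root_age below an enforced root constraint")
        out.root.age = float(root_age)
        out.root.fixed = True
    if out.root.age is None:
        raise CalibrationError("root age unknown: fix the root or pass root_age")
    out.root.fixed = True

    # bottom-up: oldest fixed descendant age B, longest free chain h,
    # and (for proportional mode) original path length to that frontier
    B, H, L = {}, {}, {}
    for nd in out.postorder():
        if nd.is_leaf:
            continue
        b = h = lng = 0.0
        for c in nd.children:
            if c.fixed and c.age is not None or c.is_leaf:
                cb, ch, cl = (c.age or 0.0), 0.0, 0.0
            else:
                cb, ch, cl = B[c], H[c] + 1, L[c]
            b = max(b, cb)
            h = max(h, ch)
            lng = max(lng, cl + (c.length if c.length is not None else 1.0))
        B[nd], H[nd], L[nd] = b, h, lng

    for nd in out.preorder():
        if nd.is_leaf or (nd.fixed and nd.age is not None):
            continue
        anc_age = nd.parent.age
        floor = B[nd]
        if anc_age < floor - 1e-12:
            raise CalibrationError(
                "fixed descendant older than its fixed ancestor "
                f"({floor:.6g} > {anc_age:.6g})"
            )
        if mode == "even":
            k = H[nd] + 1.0  # nodes remaining in this chain, self included
            nd.age = floor + (anc_age - floor) * k / (k + 1.0)
        else:
            up = nd.length if nd.length is not None else 1.0
            down = L[nd]
            nd.age = floor + (anc_age - floor) * down / (down + up)

    out.set_lengths_from_ages()
    out.check_ages()
    return out


def calibrate(tree: Phylo, constraints: AgeConstraintSet, mode: str = "even",
              root_age: float | None = None) -> Phylo:
    """Enforce minimum node ages, then ultrametricize. Convenience wrapper."""
    return ultrametricize(enforce_min_node_ages(tree, constraints), mode=mode,
                          root_age=root_age)
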