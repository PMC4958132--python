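import numpy as np
import pytest

from cultrait.supertree import (
    MRPError,
    MRPSupertree,
    _splits_key,
    encode_mrp,
    enumerate_unrooted_topologies,
    fitch_length,
    parsimony_search,
    prune_supertree,
    root_at,
    semi_strict_consensus,
)
from cultrait.tree import parse_newick, write_newick
from .conftest import brute_force_fitch


def clades(tree):
    return {tree.leafset(nd) for nd in tree.internal_nodes()}


class TestEncoding:
    def test_rooted_triplet_single_character(self):
        m = encode_mrp([parse_newick("((A,B),C);")])
        assert m.n_characters == 1
        col = dict(zip(m.taxa, m.data[:, 0]))
        assert col == {"A": 1, "B": 1, "C": 0, "Outgroup": 0}

    def test_unrooted_quartet_one_character_outgroup_missing(self):
        m = encode_mrp([parse_newick("((A,B),(C,D));")], rooted=[False])
        assert m.n_characters == 1
        col = dict(zip(m.taxa, m.data[:, 0]))
        assert col["A"] == 1 and col["B"] == 1
        assert col["C"] == 0 and col["D"] == 0
        assert col["Outgroup"] == -1  # '?' under semi-rooted coding

    def test_taxa_absent_from_source_scored_missing(self):
        m = encode_mrp([parse_newick("((A,B),C);"), parse_newick("((C,D),E);")])
        ab = [j for j in range(m.n_characters) if m.sources[j] == "source0"][0]
        col = dict(zip(m.taxa, m.data[:, ab]))
        assert col["D"] == -1 and col["E"] == -1

    def test_scaffold_characters_carry_weight(self):
        scaf = parse_newick("((A,B),(C,D));")
        m = encode_mrp([parse_newick("((A,C),B);")], scaffold=scaf,
                       scaffold_weight=100)
        w = {s: wt for s, wt in zip(m.sources, m.weights)}
        assert w["scaffold"] == 100.0
        assert w["source0"] == 1.0

    def test_duplicate_taxa_within_source_rejected(self):
        with pytest.raises(Exception):
            encode_mrp([parse_newick("((A,A),B);")])

    def test_empty_source_list_rejected(self):
        with pytest.raises(MRPError):
            encode_mrp([])


class TestFitchLength:
    def test_constant_character_zero_steps(self):
        m = encode_mrp([parse_newick("((A,B),C);")])
        m.data[:, 0] = 1
        tree = parse_newick("((A,B),(C,Outgroup));")
        assert fitch_length(tree, m) == 0.0

    def test_clean_split_one_step(self):
        m = encode_mrp([parse_newick("((A,B),(C,D));")], rooted=[False])
        tree = parse_newick("(((A,B),(C,D)),Outgroup);")
        assert fitch_length(tree, m) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_minimisation(self, seed):
        # random 6-taxon trees and characters vs brute force over labelings
        rng = np.random.default_rng(seed)
        taxa = list("ABCDEF")
        topo = enumerate_unrooted_topologies(taxa)[rng.integers(0, 105)]
        from cultrait.characters import MISSING
        from cultrait.supertree import MRPMatrix
        data = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
        data[data == 2] = MISSING
        m = MRPMatrix(taxa, data, np.ones(10), ["r"] * 10, outgroup=None)
        total = fitch_length(topo, m)
        expect = 0
        for j in range(10):
            states = {t: int(s) for t, s in zip(taxa, data[:, j])}
            expect += brute_force_fitch(topo, states)[0]
        assert total == expect

    def test_weights_multiply_steps(self):
        m = encode_mrp([parse_newick("((A,B),(C,D));")], rooted=[False])
        m.weights[:] = 7.0
        tree = parse_newick("(((A,C),(B,D)),Outgroup);")  # conflicts: 2 steps
        assert fitch_length(tree, m) == 14.0


class TestSearch:
    def test_perfect_signal_recovers_source(self):
        src = parse_newick("((((A,B),C),(D,E)),F);")
        m = encode_mrp([src])
        trees, score, _ = parsimony_search(m, n_addition_replicates=3, seed=0)
        best = root_at(trees[0], "Outgroup")
        ingroup = prune_supertree(best, list("ABCDEF"))
        assert clades(src) <= clades(ingroup) | {frozenset("ABCDEF")}

    def test_weighted_character_dominates_conflict(self):
        # scaffold quartet outweighs a conflicting source quartet
        scaf = parse_newick("((A,B),(C,D));")
        conflict = parse_newick("((A,C),(B,D));")
        m = encode_mrp([conflict], rooted=[False], scaffold=scaf,
                       scaffold_weight=100)
        trees, _, _ = parsimony_search(m, n_addition_replicates=4, seed=1)
        for t in trees:
            ing = prune_supertree(t, list("ABCD"))
            assert frozenset("AB") in clades(ing) or frozenset("CD") in clades(ing)

    def test_deterministic_given_seed(self, study_shallow):
        src = parse_newick("((((A,B),C),(D,E)),F);")
        m = encode_mrp([src])
        r1 = parsimony_search(m, n_addition_replicates=3, seed=42)
        r2 = parsimony_search(m, n_addition_replicates=3, seed=42)
        assert r1[1] == r2[1]
        assert [write_newick(t) for t in r1[0]] == [write_newick(t) for t in r2[0]]

    def test_replicate_count_validated(self):
        m = encode_mrp([parse_newick("((A,B),C);")])
        with pytest.raises(MRPError):
            parsimony_search(m, n_addition_replicates=0)

    def test_better_than_random_trees(self):
        rng = np.random.default_rng(5)
        src = [parse_newick("(((A,B),(C,D)),((E,F),G));"),
               parse_newick("((A,(B,H)),(E,G));")]
        m = encode_mrp(src)
        trees, score, _ = parsimony_search(m, n_addition_replicates=3, seed=3)
        topos = enumerate_unrooted_topologies(m.taxa[:6] + [m.taxa[-1]])
        # score of the best full search tree never exceeds random references
        for _ in range(20):
            order = list(m.taxa)
            rng.shuffle(order)
            rand = parse_newick(
                "(" + ",".join(order[:2]) + ",(" + ",".join(order[2:]) + "));"
            )
            assert score <= fitch_length(rand, m) + 1e-9


class TestConsensus:
    def test_identical_inputs_identity(self):
        t = parse_newick("(((A,B),C),D);")
        cons = semi_strict_consensus([t, t.copy()])
        assert clades(cons) == clades(t)

    def test_combinable_components_union(self):
        t1 = parse_newick("((A,B),C,D);")
        t2 = parse_newick("(A,B,(C,D));")
        cons = semi_strict_consensus([t1, t2])
        assert frozenset("AB") in clades(cons)
        assert frozenset("CD") in clades(cons)

    def test_contradiction_collapses_to_star(self):
        t1 = parse_newick("((A,B),C);")
        t2 = parse_newick("((A,C),B);")
        cons = semi_strict_consensus([t1, t2])
        assert len(cons.root.children) == 3

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(MRPError):
            semi_strict_consensus([parse_newick("((A,B),C);"),
                                   parse_newick("((A,B),D);")])


class TestPrune:
    def test_prune_is_label_bookkeeping(self):
        t = parse_newick("(((A,B),(C,D)),(E,F));")
        out = prune_supertree(t, ["A", "C", "E"])
        assert sorted(out.leaf_labels) == ["A", "C", "E"]

    def test_prune_keep_all_identity(self):
        t = parse_newick("((A,B),C);")
        assert write_newick(prune_supertree(t, ["A", "B", "C"])) == write_newick(t)


class TestModelInterface:
    def test_fit_returns_consensus_and_summary(self):
        src = [parse_newick("((((A,B),C),(D,E)),F);"),
               parse_newick("(((A,B),C),D);")]
        res = MRPSupertree(src).fit(n_replicates=3, seed=0)
        assert res.best_score >= 0
        assert set(res.consensus.leaf_labels) == set(res.model.matrix.taxa)
        assert "MRP supertree" in res.summary()

    def test_compatible_sources_all_displayed(self):
        # mutually compatible sources on overlapping taxa are all recovered
        src = [parse_newick("((A,B),C);"), parse_newick("((C,D),E);"),
               parse_newick("(((A,B),C),(D,E));")]
        res = MRPSupertree(src).fit(n_replicates=5, seed=2)
        best = res.best_trees[0]
        ing = prune_supertree(best, list("ABCDE"))
        assert frozenset("AB") in clades(ing)
        assert fitch_length(best, res.model.matrix) == res.best_score
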