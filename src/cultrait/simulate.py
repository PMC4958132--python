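"""Synthetic trees and discrete characters with the structure the analysis assumes.

Trees are pure-birth (Yule) ultrametric trees rescaled to a target depth in
kya, mirroring a calibrated supertree of a few dozen extant societies.
Characters evolve as two-state Markov chains whose stationary frequency is
matched to a target prevalence: with overall rate scale r and target
prevalence p, the gain and loss rates are q01 = r*p and q10 = r*(1-p), so
the expected tip prevalence (root drawn from the stationary distribution)
equals p.  Dependent character pairs evolve under a joint 4-state chain,
for power studies of the correlated-evolution test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .characters import STUDY_CHARACTERS, CharMatrix
from .mk import MkModel
from .pagel import simulate_binary, simulate_joint
from .tree import Phylo

#: tip prevalences of the seven religiosity characters in the study sample
STUDY_PREVALENCES = (1.00, 0.79, 0.79, 0.45, 0.24, 0.39, 0.15)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration for synthetic trees and matrices.

    ``rate_scale`` is the total switching rate q01 + q10 per kya; 0.02/kya
    on a 65 kya-deep tree gives a handful of expected changes per character,
    comparable to labile cultural traits.
    """

    n_taxa: int = 33
    depth: float = 65.0  # kya
    tree_model: str = "yule"
    characters: tuple = STUDY_CHARACTERS
    prevalences: tuple = STUDY_PREVALENCES
    rate_scale: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise SimulationError("n_taxa must be >= 3")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if len(self.characters) != len(self.prevalences):
            raise SimulationError("one prevalence per character required")
        if any(not 0 < p <= 1 for p in self.prevalences):
            raise SimulationError("prevalences must lie in (0, 1]")


def prevalence_model(p: float, rate_scale: float) -> MkModel:
    """Asymmetric model whose stationary frequency of state 1 equals ``p``.

    Prevalences are clipped to [0.005, 0.995] so that both rates stay
    positive; a target of 1.0 therefore yields a tiny but nonzero loss rate.
    """
    p = min(max(p, 0.005), 0.995)
    return MkModel(q01=rate_scale * p, q10=rate_scale * (1.0 - p),
                   root_prior="stationary")


def simulate_tree(config: SimConfig, seed: int | None = None) -> Phylo:
    """Ultrametric Yule tree with ``n_taxa`` leaves, rescaled to ``depth`` kya."""
    seed = config.seed if seed is None else seed
    if config.tree_model != "yule":
        raise SimulationError(f"unknown tree model {config.tree_model!r}")
    prng = random.Random(int(seed))
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=config.n_taxa,
        rng=prng)
    tree = Phylo.from_dendropy(dtree)
    # the generator stops exactly at the n-th birth, leaving a zero-length
    # cherry; run the clock on to the next (censored) event so every
    # terminal branch is positive while the tree stays ultrametric
    t_extra = prng.expovariate(config.n_taxa * 1.0)
    for lf in tree.leaves():
        lf.length = (lf.length or 0.0) + t_extra
    for i, lf in enumerate(tree.leaves()):
        if lf.label is None:
            lf.label = f"T{i + 1}"
    for nd in tree.preorder():
        if nd.length is None:
            nd.length = 0.0
    scale = config.depth / tree.depth
    for nd in tree.preorder():
        nd.length *= scale
    tree.root.length = None
    tree.set_ages_from_lengths()
    return tree


def simulate_matrix(tree: Phylo, config: SimConfig,
                    seed: int | None = None) -> CharMatrix:
    """Independent binary characters at the configured target prevalences."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(int(seed))
    labels = tree.leaf_labels
    cols = {}
    for name, p in zip(config.characters, config.prevalences):
        model = prevalence_model(p, config.rate_scale)
        tips = simulate_binary(tree, model, rng)
        cols[name] = [tips[l] for l in labels]
    data = np.column_stack([cols[c] for c in config.characters])
    return CharMatrix(labels, list(config.characters), data)


def simulate_dependent_pair(tree: Phylo, Q: np.ndarray, seed: int = 0,
                            root_prior=None):
    """Tip states of a coupled character pair under a 4-state generator."""
    return simulate_joint(tree, Q, seed=seed, root_prior=root_prior)
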