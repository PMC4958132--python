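"""Bundled synthetic study dataset.

The package ships a synthetic stand-in for a 33-society hunter-gatherer
religiosity dataset: a fully resolved supertree topology, a character
matrix with the seven religiosity characters (graded ancestor-worship and
high-gods columns recoded to nested present/active binaries), and two
minimum-node-age date sets (a deeper, molecular-style set and a shallower
set close to minimum divergence estimates).  All three files are
constructed, not transcribed from any archived study data; they match the
published sample only in its summary structure — taxon count, the seven
tip prevalences (100/79/79/45/24/39/15%), the deep African/non-African
split, the deepest-rooting non-African lineage, and the qualitative trait
geography described in the text.  File integrity is verified by SHA-256
checksums at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

from .characters import CharMatrix, derive_binary_traits
from .tree import AgeConstraintSet, Phylo, calibrate, parse_newick

DATE_SETS = ("shallow", "deep")
AFRICAN_SOCIETIES = ("Hadza", "Sandawe", "Kung", "Gwi", "Mbuti", "Aka")

_FILES = {
    "topology": "synthetic_study_topology.nwk",
    "matrix": "synthetic_study_matrix.csv",
    "constraints": "synthetic_age_constraints.tsv",
}


class FixtureIntegrityError(RuntimeError):
    pass


def _data_path(name):
    return resources.files("cultrait.data") / name


def _verify_checksums():
    with (_data_path("checksums.json")).open() as fh:
        expected = json.load(fh)
    for key, fname in _FILES.items():
        digest = hashlib.sha256(_data_path(fname).read_bytes()).hexdigest()
        if digest != expected[fname]:
            raise FixtureIntegrityError(
                f"checksum mismatch for bundled file {fname!r}"
            )


def load_study_fixture(dates: str = "shallow"):
    """Load the synthetic study dataset, calibrated under one date set.

    Returns ``(tree, matrix, constraints)``: an ultrametric tree over the
    33 societies plus the all-absent hypothetical outgroup, the 34 x 7
    binary character matrix, and the age-constraint set used.
    """
    if dates not in DATE_SETS:
        raise ValueError(f"dates must be one of {DATE_SETS}")
    _verify_checksums()
    topo = parse_newick(_data_path(_FILES["topology"]).read_text())
    raw = CharMatrix.from_csv(_data_path(_FILES["matrix"]))
    matrix = derive_binary_traits(raw).attach_outgroup()
    constraints = AgeConstraintSet.from_tsv(_data_path(_FILES["constraints"]),
                                            date_set=dates)
    tree = calibrate(topo, constraints)
    extra = set(tree.leaf_labels) ^ set(matrix.taxa)
    if extra:
        raise FixtureIntegrityError(f"tree/matrix taxon mismatch: {sorted(extra)}")
    return tree, matrix, constraints
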