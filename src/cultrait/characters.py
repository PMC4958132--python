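"""Discrete character matrices for cross-cultural trait data.

A :class:`CharMatrix` holds an ordered taxa-by-characters table of discrete
states: binary characters use {0, 1}, SCCS-style graded characters use
{1..4}, and ``?`` marks missing data.  Graded characters can be recoded to
nested presence/activity binaries (present <=> state >= 2, active <=> state
>= 3), the recoding used for ancestor worship and high gods in the seven
religiosity characters this package was built around.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

MISSING = -1  # internal code for '?'

#: canonical order of the seven religiosity characters
STUDY_CHARACTERS = (
    "animism",
    "afterlife",
    "shamanism",
    "ancestor_worship",
    "active_ancestor_worship",
    "high_gods",
    "active_high_gods",
)

DEFAULT_OUTGROUP = "Outgroup"


class CharacterError(ValueError):
    pass


def _encode_cell(v):
    if isinstance(v, str):
        v = v.strip()
        if v in ("?", "", "-", "NA"):
            return MISSING
        return int(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return MISSING
    return int(v)


class CharMatrix:
    """Rectangular taxa x characters matrix of small integer states.

    Parameters
    ----------
    taxa : ordered taxon labels (unique)
    characters : ordered character names (unique)
    data : array-like of shape (n_taxa, n_characters); ``?``/NaN become missing
    outgroup : label of the hypothetical outgroup row, if one is attached
    """

    def __init__(self, taxa, characters, data, outgroup: str | None = None):
        self.taxa = list(taxa)
        self.characters = list(characters)
        arr = np.empty((len(self.taxa), len(self.characters)), dtype=np.int8)
        data = np.asarray(data, dtype=object)
        if data.shape != arr.shape:
            raise CharacterError(
                f"data shape {data.shape} != ({len(self.taxa)}, {len(self.characters)})"
            )
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                arr[i, j] = _encode_cell(data[i, j])
        self.data = arr
        self.outgroup = outgroup
        if len(set(self.taxa)) != len(self.taxa):
            raise CharacterError("duplicate taxon labels")
        if len(set(self.characters)) != len(self.characters):
            raise CharacterError("duplicate character names")
        if outgroup is not None and outgroup not in self.taxa:
            raise CharacterError(f"outgroup {outgroup!r} not among taxa")

    # -- basic access ----------------------------------------------------

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_characters(self):
        return len(self.characters)

    def _cidx(self, character):
        try:
            return self.characters.index(character)
        except ValueError:
            raise CharacterError(f"unknown character {character!r}") from None

    def column(self, character) -> np.ndarray:
        return self.data[:, self._cidx(character)].copy()

    def states_dict(self, character, include_outgroup: bool = True) -> dict:
        """Map taxon -> state (missing entries keep code -1)."""
        col = self.column(character)
        return {
            t: int(s)
            for t, s in zip(self.taxa, col)
            if include_outgroup or t != self.outgroup
        }

    def is_binary(self, character) -> bool:
        col = self.column(character)
        return bool(np.all(np.isin(col, (0, 1, MISSING))))

    def copy(self) -> "CharMatrix":
        return CharMatrix(self.taxa, self.characters, self.data.copy(),
                          outgroup=self.outgroup)

    # -- summaries -------------------------------------------------------

    def prevalence(self, character) -> float:
        """Percent of scored ingroup taxa in state 1 (missing excluded)."""
        j = self._cidx(character)
        rows = [i for i, t in enumerate(self.taxa) if t != self.outgroup]
        col = self.data[rows, j]
        scored = col != MISSING
        if not scored.any():
            raise CharacterError(f"character {character!r} has no scored taxa")
        if not self.is_binary(character):
            raise CharacterError(f"character {character!r} is not binary")
        return 100.0 * float((col[scored] == 1).sum()) / float(scored.sum())

    def prevalences(self, round_half_up: bool = True) -> dict:
        """Prevalence of every binary character, rounded half-up to whole %."""
        out = {}
        for ch in self.characters:
            p = self.prevalence(ch)
            out[ch] = int(np.floor(p + 0.5)) if round_half_up else p
        return out

    # -- transforms ------------------------------------------------------

    def attach_outgroup(self, label: str = DEFAULT_OUTGROUP) -> "CharMatrix":
        """Append a hypothetical all-absent (state 0) outgroup row."""
        if self.outgroup is not None:
            raise CharacterError(f"outgroup {self.outgroup!r} already attached")
        if label in self.taxa:
            raise CharacterError(f"taxon label {label!r} collides with an existing taxon")
        data = np.vstack([self.data, np.zeros((1, self.n_characters), dtype=np.int8)])
        return CharMatrix(self.taxa + [label], self.characters, data, outgroup=label)

    def drop_outgroup(self) -> "CharMatrix":
        if self.outgroup is None:
            return self.copy()
        rows = [i for i, t in enumerate(self.taxa) if t != self.outgroup]
        return CharMatrix([self.taxa[i] for i in rows], self.characters,
                          self.data[rows], outgroup=None)

    def subset(self, characters) -> "CharMatrix":
        idx = [self._cidx(c) for c in characters]
        return CharMatrix(self.taxa, list(characters), self.data[:, idx],
                          outgroup=self.outgroup)

    # -- I/O -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.taxa, columns=self.characters)
        return df.replace(MISSING, pd.NA)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outgroup=None) -> "CharMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=object),
                   outgroup=outgroup)

    def to_csv(self, path):
        df = self.to_dataframe().fillna("?")
        df.index.name = "taxon"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, outgroup=None) -> "CharMatrix":
        df = pd.read_csv(path, index_col=0, dtype=object, keep_default_na=False)
        return cls.from_dataframe(df, outgroup=outgroup)

    def to_nexus(self, path):
        sym = "".join(sorted({str(s) for s in np.unique(self.data) if s != MISSING}))
        dmat = dendropy.StandardCharacterMatrix()
        dmat.default_state_alphabet = dendropy.new_standard_state_alphabet(sym)
        tns = dmat.taxon_namespace
        for i, t in enumerate(self.taxa):
            tax = tns.require_taxon(label=t)
            row = "".join(
                "?" if s == MISSING else str(int(s)) for s in self.data[i]
            )
            dmat[tax] = row
        dmat.write(path=str(path), schema="nexus")

    @classmethod
    def from_nexus(cls, path, outgroup=None) -> "CharMatrix":
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        taxa, rows = [], []
        for tax in dmat.taxon_namespace:
            taxa.append(tax.label)
            rows.append([str(cell) for cell in dmat[tax].symbols_as_list()])
        ncols = len(rows[0]) if rows else 0
        chars = [f"char{j+1}" for j in range(ncols)]
        return cls(taxa, chars, rows, outgroup=outgroup)

    def __repr__(self):  # pragma: no cover
        return f"<CharMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


def binarize_graded(matrix: CharMatrix, character: str, present_name: str,
                    active_name: str, present_threshold: int = 2,
                    active_threshold: int = 3) -> CharMatrix:
    """Recode one 4-state graded character into nested presence/activity binaries.

    State 1 is absence; the trait is *present* from ``present_threshold``
    upward and *active* from ``active_threshold`` upward, so the active
    binary implies the present binary for every taxon.
    """
    col = matrix.column(character)
    bad = ~np.isin(col, (1, 2, 3, 4, MISSING))
    if bad.any():
        raise CharacterError(
            f"{character!r}: states outside 1..4 at "
            f"{[matrix.taxa[i] for i in np.where(bad)[0]]}"
        )
    present = np.where(col == MISSING, MISSING, (col >= present_threshold).astype(np.int8))
    active = np.where(col == MISSING, MISSING, (col >= active_threshold).astype(np.int8))
    j = matrix._cidx(character)
    names, cols = [], []
    for k, name in enumerate(matrix.characters):
        if k == j:
            names.extend([present_name, active_name])
            cols.extend([present, active])
        else:
            names.append(name)
            cols.append(matrix.data[:, k])
    return CharMatrix(matrix.taxa, names, np.column_stack(cols),
                      outgroup=matrix.outgroup)


def derive_binary_traits(raw: CharMatrix) -> CharMatrix:
    """Recode the study layout: graded ancestor worship and high gods columns
    become present/active binary pairs, yielding the seven-character matrix."""
    out = raw
    if "ancestor_worship" in out.characters and not out.is_binary("ancestor_worship"):
        out = binarize_graded(out, "ancestor_worship",
                              "ancestor_worship", "active_ancestor_worship")
    if "high_gods" in out.characters and not out.is_binary("high_gods"):
        out = binarize_graded(out, "high_gods", "high_gods", "active_high_gods")
    order = [c for c in STUDY_CHARACTERS if c in out.characters] + [
        c for c in out.characters if c not in STUDY_CHARACTERS
    ]
    return out.subset(order)


def attach_outgroup(matrix: CharMatrix, label: str = DEFAULT_OUTGROUP) -> CharMatrix:
    return matrix.attach_outgroup(label)


def prevalence(matrix: CharMatrix, character: str) -> float:
    return matrix.prevalence(character)
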