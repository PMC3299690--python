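"""Ordered multistate character coding of substructure lengths.

Segment lengths are mapped onto a 64-symbol linearly ordered alphabet
(digits, upper case, lower case, ``@``, ``&``); state index equals length,
saturating at the maximum state ``&``.  Characters are polarized by
declaring an ancestral state per character — by default the maximum
observed state, encoding the assumption that longer, more structurally
ordered segments are ancestral.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, InputError
from .structures import HomologyTemplate, slot_lengths


@dataclass(frozen=True)
class StateAlphabet:
    """A linearly ordered state alphabet; index = rank of the symbol."""

    symbols: str

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise InputError("alphabet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise DomainError(f"symbol {symbol!r} outside alphabet") from None

    def symbol(self, index: int) -> str:
        if not 0 <= index < len(self.symbols):
            raise DomainError(f"state index {index} outside alphabet")
        return self.symbols[index]

    def encode_length(self, length: int, cap_at: int | None = None) -> str:
        """Symbol whose index is ``min(length, cap)``; cap defaults to the top state."""
        if length < 0:
            raise DomainError(f"negative length {length}")
        cap = len(self.symbols) - 1 if cap_at is None else cap_at
        return self.symbols[min(length, cap)]


#: digits, upper case, lower case, '@', '&' — 64 ordered states
RRNA_ALPHABET = StateAlphabet(
    string.digits + string.ascii_uppercase + string.ascii_lowercase + "@&"
)

#: digits then A–K — the 21 ordered states of genomic-abundance gap coding
CENSUS_ALPHABET = StateAlphabet(string.digits + "ABCDEFGHIJK")


def encode_length(length: int, alphabet: StateAlphabet = RRNA_ALPHABET, cap_at: int | None = None) -> str:
    """Encode a segment length as an ordered-state symbol (saturating)."""
    return alphabet.encode_length(length, cap_at=cap_at)


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters grid of ordered multistate symbols.

    ``rows`` label the grid rows, ``characters`` the columns.  The matrix
    may be held in either orientation (organisms as rows, or substructures
    as rows for tree building); :func:`transpose_matrix` flips it.
    """

    rows: tuple
    characters: tuple
    states: tuple  # tuple of row strings, one symbol per character
    alphabet: StateAlphabet = RRNA_ALPHABET
    ordered: bool = True
    ancestral_states: str | None = None

    def __post_init__(self):
        if len(self.states) != len(self.rows):
            raise InputError("state grid rows != row labels")
        for r in self.states:
            if len(r) != len(self.characters):
                raise InputError("ragged state grid")
            for c in r:
                if c not in self.alphabet:
                    raise DomainError(f"symbol {c!r} outside alphabet")
        if self.ancestral_states is not None:
            if len(self.ancestral_states) != len(self.characters):
                raise InputError("ancestral_states length != character count")
            for c in self.ancestral_states:
                if c not in self.alphabet:
                    raise DomainError(f"ancestral symbol {c!r} outside alphabet")
        if len(set(self.rows)) != len(self.rows):
            raise InputError("duplicate row labels")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, label: str) -> str:
        try:
            return self.states[self.rows.index(label)]
        except ValueError:
            raise InputError(f"unknown row label {label!r}") from None

    def indices(self) -> np.ndarray:
        """Integer state-index array, shape (n_rows, n_characters)."""
        lut = {s: i for i, s in enumerate(self.alphabet.symbols)}
        return np.array([[lut[c] for c in r] for r in self.states], dtype=np.int64)

    def ancestral_indices(self) -> np.ndarray:
        if self.ancestral_states is None:
            raise InputError("matrix has no ancestral states")
        lut = {s: i for i, s in enumerate(self.alphabet.symbols)}
        return np.array([lut[c] for c in self.ancestral_states], dtype=np.int64)

    def informative_characters(self) -> list:
        """Characters with at least two states each seen in >= 2 rows."""
        keep = []
        for j, char in enumerate(self.characters):
            col = [r[j] for r in self.states]
            counts = {c: col.count(c) for c in set(col)}
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                keep.append(char)
        return keep


def build_matrix(
    template: HomologyTemplate,
    structures,
    orientation: str = "molecule_rows",
    alphabet: StateAlphabet = RRNA_ALPHABET,
    cap_at: int | None = None,
) -> CharacterMatrix:
    """Code template-aligned structures into a character matrix.

    ``molecule_rows``: rows are organisms, columns are slots in 5'->3'
    order.  ``substructure_rows``: the exact transpose (rows are slots),
    the orientation used to build trees of substructures.  Absent slots
    (length 0) encode as the minimum state.
    """
    if orientation not in ("molecule_rows", "substructure_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    if not template.slots:
        raise InputError("empty homology template")
    if not structures:
        raise InputError("no structures to code")
    slot_ids = template.slot_ids
    taxa = tuple(s.name for s in structures)
    grid = []
    for s in structures:
        lengths = slot_lengths(template, s)
        grid.append("".join(alphabet.encode_length(lengths[sid], cap_at=cap_at) for sid in slot_ids))
    m = CharacterMatrix(
        rows=taxa, characters=tuple(slot_ids), states=tuple(grid), alphabet=alphabet
    )
    if orientation == "substructure_rows":
        m = transpose_matrix(m)
    return m


def select_characters(m: CharacterMatrix, characters) -> CharacterMatrix:
    """Restrict a matrix to the named characters, preserving their order."""
    idx = []
    for c in characters:
        if c not in m.characters:
            raise InputError(f"unknown character {c!r}")
        idx.append(m.characters.index(c))
    states = tuple("".join(row[j] for j in idx) for row in m.states)
    anc = None
    if m.ancestral_states is not None:
        anc = "".join(m.ancestral_states[j] for j in idx)
    return CharacterMatrix(
        rows=m.rows,
        characters=tuple(characters),
        states=states,
        alphabet=m.alphabet,
        ordered=m.ordered,
        ancestral_states=anc,
    )


def transpose_matrix(m: CharacterMatrix) -> CharacterMatrix:
    """Swap rows and columns; ancestral states (per character) are dropped."""
    states = tuple(
        "".join(m.states[i][j] for i in range(m.n_rows)) for j in range(m.n_characters)
    )
    return CharacterMatrix(
        rows=m.characters,
        characters=m.rows,
        states=states,
        alphabet=m.alphabet,
        ordered=m.ordered,
    )


def polarize(m: CharacterMatrix, rule: str = "max_ancestral") -> CharacterMatrix:
    """Attach an ancestral state to every character.

    ``max_ancestral`` (default): the maximum observed state in the
    character is declared ancestral — the study's polarization towards
    decreasing structural order.  ``min_ancestral`` is the reverse;
    ``fixed:<symbol>`` declares one symbol for all characters.
    """
    idx = m.indices()
    if rule == "max_ancestral":
        anc = [m.alphabet.symbol(int(v)) for v in idx.max(axis=0)]
    elif rule == "min_ancestral":
        anc = [m.alphabet.symbol(int(v)) for v in idx.min(axis=0)]
    elif rule.startswith("fixed:"):
        sym = rule.split(":", 1)[1]
        if sym not in m.alphabet:
            raise DomainError(f"fixed ancestral symbol {sym!r} outside alphabet")
        anc = [sym] * m.n_characters
    else:
        raise InputError(f"unknown polarization rule {rule!r}")
    return replace(m, ancestral_states="".join(anc))
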