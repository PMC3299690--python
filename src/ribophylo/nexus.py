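"""Minimal NEXUS export/import for ordered multistate character matrices.

The DATA block carries the symbol list verbatim; the ASSUMPTIONS block
declares all characters ordered (``OPTIONS DEFTYPE=ORD``) and, when the
matrix is polarized, the per-character ancestral states on a single
``ANCSTATES`` line.  The reader accepts exactly what the writer emits, so
write/read is an identity on valid matrices.
"""

from __future__ import annotations

import re

from .coding import CharacterMatrix, StateAlphabet
from .errors import DomainError, FormatError

_SAFE_NAME = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _quote(name: str) -> str:
    if _SAFE_NAME.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def write_character_matrix(m: CharacterMatrix, path) -> None:
    """Write a NEXUS file with DATA and ASSUMPTIONS blocks."""
    for row in m.states:
        for c in row:
            if c not in m.alphabet:
                raise DomainError(f"symbol {c!r} outside alphabet")
    width = max(len(_quote(t)) for t in m.rows)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_rows} NCHAR={m.n_characters};",
        f'    FORMAT SYMBOLS="{m.alphabet.symbols}" MISSING=? GAP=-;',
        "    CHARLABELS " + " ".join(_quote(c) for c in m.characters) + ";",
        "    MATRIX",
    ]
    for taxon, row in zip(m.rows, m.states):
        lines.append(f"    {_quote(taxon):<{width}}  {row}")
    lines += ["    ;", "END;", "BEGIN ASSUMPTIONS;"]
    lines.append(f"    OPTIONS DEFTYPE={'ORD' if m.ordered else 'UNORD'};")
    if m.ancestral_states is not None:
        lines.append(f"    ANCSTATES * ancestral = {m.ancestral_states};")
    lines += ["END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _unquote(token: str) -> str:
    if token.startswith("'") and token.endswith("'"):
        return token[1:-1].replace("''", "'")
    return token


def read_character_matrix(path) -> CharacterMatrix:
    """Read a NEXUS file written by :func:`write_character_matrix`."""
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise FormatError(f"{path}: not a NEXUS file")
    m_sym = re.search(r'SYMBOLS="([^"]+)"', text)
    if not m_sym:
        raise FormatError(f"{path}: no SYMBOLS declaration")
    alphabet = StateAlphabet(m_sym.group(1))
    m_dim = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+)", text, re.I)
    if not m_dim:
        raise FormatError(f"{path}: no DIMENSIONS declaration")
    ntax, nchar = int(m_dim.group(1)), int(m_dim.group(2))
    m_mat = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not m_mat:
        raise FormatError(f"{path}: no MATRIX block")
    taxa, rows = [], []
    for ln in m_mat.group(1).splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("'"):
            m_q = re.match(r"^('(?:[^']|'')*')\s+(\S+)$", ln)
            if not m_q:
                raise FormatError(f"{path}: malformed matrix row {ln!r}")
            name, row = _unquote(m_q.group(1)), m_q.group(2)
        else:
            parts = ln.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed matrix row {ln!r}")
            name, row = parts
        taxa.append(name)
        rows.append(row)
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise FormatError(f"{path}: matrix dimensions disagree with DIMENSIONS")
    ordered = True
    m_opt = re.search(r"DEFTYPE=(\w+)", text, re.I)
    if m_opt:
        ordered = m_opt.group(1).upper() == "ORD"
    anc = None
    m_anc = re.search(r"ANCSTATES\s*\*?\s*\w+\s*=\s*(\S+?);", text, re.I)
    if m_anc:
        anc = m_anc.group(1)
    chars = tuple(f"c{j + 1}" for j in range(nchar))
    m_cl = re.search(r"CHARLABELS(.*?);", text, re.S | re.I)
    if m_cl:
        tokens = re.findall(r"'(?:[^']|'')*'|\S+", m_cl.group(1))
        if len(tokens) == nchar:
            chars = tuple(_unquote(t) for t in tokens)
    return CharacterMatrix(
        rows=tuple(taxa),
        characters=chars,
        states=tuple(rows),
        alphabet=alphabet,
        ordered=ordered,
        ancestral_states=anc,
    )
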