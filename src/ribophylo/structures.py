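"""RNA secondary structures, S/H/B/U decomposition, and structural alignments.

The unit of information throughout the package is the *substructure*: a
helical stem (S), hairpin loop (H), bulge/interior loop (B) or unpaired
segment (U) of an RNA secondary structure.  A *helix region* is a run of
stacked stems separated from the rest of the molecule by multibranched
loops or pseudoknot boundaries; it may contain internal bulges and
interior loops.  Homologous regions across taxa are described by a
:class:`HomologyTemplate`, whose slots carry column ranges in a master
alignment; the per-slot segment lengths are the raw data from which
phylogenetic characters are coded (see :mod:`ribophylo.coding`).

Coordinates are 1-based closed intervals.  Gap characters ``-`` in aligned
sequences contribute 0 to segment lengths.  Pseudoknotted pairs (written
with ``[]``, ``{}`` or ``<>`` brackets) are accepted on parse but act only
as helix-region delimiters, never as stems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    AlignmentError,
    FormatError,
    InputError,
    StructureParseError,
)

RNA_ALPHABET = set("ACGUN-")

_OPEN = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_PK_OPEN = set("[{<")


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with a nested base-pair map.

    ``pairs`` holds 1-based ``(i, j)`` with ``i < j``; ``pseudoknot_pairs``
    holds extra pairs that may cross the nested set.
    """

    name: str
    sequence: str
    pairs: frozenset
    pseudoknot_pairs: frozenset = frozenset()

    def __post_init__(self):
        n = len(self.sequence)
        seen = set()
        for i, j in self.pairs | self.pseudoknot_pairs:
            if not (1 <= i < j <= n):
                raise InputError(f"pair ({i},{j}) out of range for length {n}")
            if i in seen or j in seen:
                raise InputError(f"position in more than one pair: ({i},{j})")
            seen.add(i)
            seen.add(j)
        _check_nested(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def partner(self) -> dict:
        """Position -> paired position, nested pairs only."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def validate(self, min_hairpin: int = 3) -> None:
        """Raise if any nested pair encloses fewer than ``min_hairpin`` bases."""
        for i, j in self.pairs:
            if j - i - 1 < min_hairpin:
                raise InputError(
                    f"pair ({i},{j}) encloses {j - i - 1} < {min_hairpin} bases"
                )

    def dotbracket(self) -> str:
        out = ["."] * len(self.sequence)
        for i, j in self.pairs:
            out[i - 1], out[j - 1] = "(", ")"
        for i, j in self.pseudoknot_pairs:
            out[i - 1], out[j - 1] = "[", "]"
        for k, c in enumerate(self.sequence):
            if c == "-":
                out[k] = "-"
        return "".join(out)


def _check_nested(pairs):
    stack = []
    events = []
    for i, j in pairs:
        events.append((i, 0, j))
        events.append((j, 1, i))
    events.sort()
    for pos, kind, other in events:
        if kind == 0:
            stack.append((pos, other))
        else:
            if not stack or stack[-1][1] != pos:
                raise InputError(
                    f"crossing (pseudoknotted) pairs in nested pair set near {pos}"
                )
            stack.pop()


@dataclass(frozen=True)
class Substructure:
    """One S/H/B/U segment.

    S carries two equal-length spans (the complementary strands); H, B and
    U carry one.  ``length`` is base pairs for S and nucleotides otherwise.
    """

    id: str
    kind: str
    segments: tuple
    length: int

    def __post_init__(self):
        if self.kind not in "SHBU":
            raise InputError(f"unknown substructure kind {self.kind!r}")
        if self.kind == "S":
            if len(self.segments) != 2:
                raise InputError("S substructure needs exactly two spans")
            (a, b), (c, d) = self.segments
            if b - a != d - c:
                raise InputError("S spans must have equal length")
        elif len(self.segments) != 1:
            raise InputError(f"{self.kind} substructure needs exactly one span")

    @property
    def start(self) -> int:
        return self.segments[0][0]


def parse_dotbracket(structure: str, sequence: str, name: str = "") -> SecondaryStructure:
    """Parse a Vienna dot-bracket line against its sequence.

    ``()`` brackets form the nested pair map; ``[]``, ``{}`` and ``<>``
    are pseudoknot pairs.  ``.``, ``:`` and ``-`` are unpaired/gap.
    """
    if len(structure) != len(sequence):
        raise InputError(
            f"structure length {len(structure)} != sequence length {len(sequence)}"
        )
    bad = set(sequence.upper()) - RNA_ALPHABET
    if bad:
        raise InputError(f"sequence characters outside A/C/G/U/N/-: {sorted(bad)}")
    stacks: dict[str, list] = {c: [] for c in _OPEN}
    pairs, pk_pairs = set(), set()
    for pos, c in enumerate(structure, start=1):
        if c in _OPEN:
            stacks[c].append(pos)
        elif c in _CLOSE:
            opener = _CLOSE[c]
            if not stacks[opener]:
                raise StructureParseError(f"unmatched {c!r}", position=pos)
            i = stacks[opener].pop()
            (pk_pairs if opener in _PK_OPEN else pairs).add((i, pos))
        elif c not in ".:-,_":
            raise StructureParseError(f"unknown structure character {c!r}", position=pos)
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(f"unmatched {opener!r}", position=stack[-1])
    return SecondaryStructure(
        name=name,
        sequence=sequence.upper(),
        pairs=frozenset(pairs),
        pseudoknot_pairs=frozenset(pk_pairs),
    )


def read_vienna(path) -> list[SecondaryStructure]:
    """Read FASTA-like Vienna records: ``>name``, sequence line, structure line."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(f"truncated record {lines[i][1:]!r}")
        records.append(parse_dotbracket(lines[i + 2], lines[i + 1], name=lines[i][1:].strip()))
        i += 3
    return records


def write_vienna(structures, path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.name}\n{s.sequence}\n{s.dotbracket()}\n")


# ---------------------------------------------------------------------------
# Decomposition into S/H/B/U
# ---------------------------------------------------------------------------

def _ladders(pairs):
    """Group nested pairs into maximal stacked runs (ladders).

    Returns a list of lists of pairs, each sorted outside-in.
    """
    pairs = sorted(pairs)
    ladders = []
    current = []
    for p in pairs:
        if current and (p[0] == current[-1][0] + 1 and p[1] == current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                ladders.append(current)
            current = [p]
    if current:
        ladders.append(current)
    return ladders


def decompose_structure(s: SecondaryStructure, template: "HomologyTemplate | None" = None):
    """Decompose a structure into S/H/B/U substructures, 5'->3'.

    Without a template, helix regions are inferred from the pair map: a
    region is a chain of ladders linked through unpaired (bulge/interior)
    runs, broken by multiloops and by pseudoknotted positions.  With a
    template, the structure must be aligned to the template columns and
    lengths are the non-gap counts inside each slot's column range.

    The result is a partition: every sequence position belongs to exactly
    one substructure (stem positions to their S, counting both strands).
    """
    if template is not None:
        return _decompose_with_template(s, template)

    n = len(s.sequence)
    paired = set()
    for i, j in s.pairs:
        paired.add(i)
        paired.add(j)
    pk = set()
    for i, j in s.pseudoknot_pairs:
        pk.add(i)
        pk.add(j)

    ladders = _ladders(s.pairs)

    def run_clean(a, b):
        """True if positions a..b are all unpaired and non-pseudoknotted."""
        return all(p not in paired and p not in pk for p in range(a, b + 1))

    # chain ladders into helix regions: inner ladder follows outer iff the
    # two flanking runs are clean (pure bulge/interior loop)
    inner_of = {}
    for k, lad in enumerate(ladders):
        a, b = lad[-1]  # innermost pair of this ladder
        nxt = None
        for m, cand in enumerate(ladders):
            ci, cj = cand[0]
            if a < ci and cj < b:
                if run_clean(a + 1, ci - 1) and run_clean(cj + 1, b - 1):
                    # candidate must be the outermost ladder directly inside
                    nxt = m
                break  # ladders sorted by start; first nested one decides
        if nxt is not None:
            inner_of[k] = nxt
    chained = set(inner_of.values())
    regions = []
    for k in range(len(ladders)):
        if k in chained:
            continue
        chain = [k]
        while chain[-1] in inner_of:
            chain.append(inner_of[chain[-1]])
        regions.append(chain)
    regions.sort(key=lambda ch: ladders[ch[0]][0][0])

    subs = []
    assigned = set()
    for rnum, chain in enumerate(regions, start=1):
        rid = f"R{rnum}"
        s_count = b_count = 0
        for depth, k in enumerate(chain):
            lad = ladders[k]
            s_count += 1
            (i0, j0), (i1, j1) = lad[0], lad[-1]
            subs.append(
                Substructure(
                    id=f"{rid}.S{s_count}",
                    kind="S",
                    segments=((i0, i1), (j1, j0)),
                    length=len(lad),
                )
            )
            for p in lad:
                assigned.update(p)
            inner = chain[depth + 1] if depth + 1 < len(chain) else None
            if inner is not None:
                ci, cj = ladders[inner][0]
                for a, b in ((i1 + 1, ci - 1), (cj + 1, j1 - 1)):
                    if a <= b:
                        b_count += 1
                        subs.append(
                            Substructure(
                                id=f"{rid}.B{b_count}",
                                kind="B",
                                segments=((a, b),),
                                length=b - a + 1,
                            )
                        )
                        assigned.update(range(a, b + 1))
            else:
                a, b = i1 + 1, j1 - 1
                if a <= b and run_clean(a, b):
                    subs.append(
                        Substructure(
                            id=f"{rid}.H1",
                            kind="H",
                            segments=((a, b),),
                            length=b - a + 1,
                        )
                    )
                    assigned.update(range(a, b + 1))

    # everything left (exterior, multiloops, pseudoknot-containing runs) -> U
    u_count = 0
    pos = 1
    while pos <= n:
        if pos in assigned:
            pos += 1
            continue
        start = pos
        while pos <= n and pos not in assigned:
            pos += 1
        u_count += 1
        subs.append(
            Substructure(
                id=f"U{u_count}",
                kind="U",
                segments=((start, pos - 1),),
                length=pos - start,
            )
        )
    subs.sort(key=lambda x: x.start)
    return subs


def _gapless_len(seq: str, a: int, b: int) -> int:
    if a > b:
        return 0
    return sum(1 for c in seq[a - 1 : b] if c != "-")


def _decompose_with_template(s, template):
    ncols = template.n_columns
    if len(s.sequence) != ncols:
        raise AlignmentError(
            f"structure {s.name!r} has {len(s.sequence)} columns, template has {ncols}"
        )
    subs = []
    for slot in template.slots:
        a, b = slot.columns
        length = _gapless_len(s.sequence, a, b)
        if slot.kind == "S":
            pa, pb = template.slot(slot.partner).columns
            plen = _gapless_len(s.sequence, pa, pb)
            if plen != length:
                raise AlignmentError(
                    f"stem slot {slot.slot_id} has unequal strand lengths "
                    f"({length} vs {plen}) in {s.name!r}"
                )
            if slot.slot_id.endswith("'"):
                continue  # primed strand reported with its partner
            segs = ((a, b), (pa, pb)) if a <= pa else ((pa, pb), (a, b))
            subs.append(Substructure(id=slot.slot_id, kind="S", segments=segs, length=length))
        else:
            subs.append(
                Substructure(id=slot.slot_id, kind=slot.kind, segments=((a, b),), length=length)
            )
    subs.sort(key=lambda x: x.start)
    return subs


# ---------------------------------------------------------------------------
# Homology template & helix-map TSV
# ---------------------------------------------------------------------------

_SLOT_RE = re.compile(r"^(?P<region>[^.]+)\.(?P<kind>[SHBU])(?P<index>\d+)(?P<prime>')?$")


@dataclass(frozen=True)
class TemplateSlot:
    slot_id: str
    region: str
    kind: str
    columns: tuple  # (start, end) 1-based closed; start > end means empty
    partner: str | None = None  # primed partner for S slots


@dataclass
class HomologyTemplate:
    """Ordered S/B/H/U slots per helix region, with master-alignment columns."""

    slots: list = field(default_factory=list)
    aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        prev_end = 0
        for slot in self.slots:
            a, b = slot.columns
            if a <= b:
                if a <= prev_end:
                    raise InputError(
                        f"template columns not disjoint/ascending at {slot.slot_id}"
                    )
                prev_end = b
            if slot.kind == "S" and slot.partner is None:
                raise InputError(f"stem slot {slot.slot_id} lacks a primed partner")

    @property
    def regions(self) -> list:
        seen = []
        for slot in self.slots:
            if slot.region not in seen:
                seen.append(slot.region)
        return seen

    @property
    def slot_ids(self) -> list:
        return [s.slot_id for s in self.slots]

    @property
    def n_columns(self) -> int:
        return max((s.columns[1] for s in self.slots if s.columns[0] <= s.columns[1]), default=0)

    def slot(self, slot_id: str) -> TemplateSlot:
        slot_id = self.aliases.get(slot_id, slot_id)
        for s in self.slots:
            if s.slot_id == slot_id:
                return s
        raise InputError(f"unknown slot id {slot_id!r}")


def parse_slot_id(slot_id: str):
    m = _SLOT_RE.match(slot_id)
    if not m:
        raise FormatError(f"malformed slot id {slot_id!r} (expected e.g. 'h44.S1')")
    return m.group("region"), m.group("kind"), int(m.group("index")), bool(m.group("prime"))


def _template_from_lengths(slot_ids, lengths_by_taxon):
    """Build a template whose column widths are the per-slot maxima."""
    slots = []
    col = 1
    for sid in slot_ids:
        region, kind, index, prime = parse_slot_id(sid)
        width = max(lengths_by_taxon[t][sid] for t in lengths_by_taxon)
        partner = None
        if kind == "S":
            partner = sid[:-1] if prime else sid + "'"
        slots.append(
            TemplateSlot(
                slot_id=sid,
                region=region,
                kind=kind,
                columns=(col, col + width - 1),
                partner=partner,
            )
        )
        col += width
    return HomologyTemplate(slots=slots)


_STEM_BASE = {"S5": "G", "S3": "C"}


def _canonical_structure(name, template, lengths):
    """Synthesize an aligned structure realizing the given slot lengths."""
    ncols = template.n_columns
    seq = ["-"] * ncols
    pairs = set()
    open_cols: dict[str, list] = {}
    for slot in template.slots:
        a, b = slot.columns
        k = lengths[slot.slot_id]
        if slot.kind == "S" and not slot.slot_id.endswith("'"):
            cols = list(range(a, a + k))
            open_cols[slot.slot_id] = cols
            for c in cols:
                seq[c - 1] = "G"
        elif slot.kind == "S":
            cols = list(range(b - k + 1, b + 1))
            if slot.partner not in open_cols:
                raise FormatError(
                    f"primed stem slot {slot.slot_id} precedes its partner {slot.partner}"
                )
            partner_cols = open_cols[slot.partner]
            if len(partner_cols) != k:
                raise FormatError(
                    f"stem {slot.partner}/{slot.slot_id} lengths differ for {name!r}"
                )
            for c, pc in zip(reversed(cols), partner_cols):
                pairs.add((pc, c))
                seq[c - 1] = "C"
        else:
            for c in range(a, a + k):
                seq[c - 1] = "A"
    return SecondaryStructure(name=name, sequence="".join(seq), pairs=frozenset(pairs))


def load_structural_alignment(path):
    """Read a helix-map TSV into a template and aligned canonical structures.

    Dialect: header ``taxon<TAB><slot_id>...``; one row per taxon; cells are
    segment lengths (integer >= 0).  Stem slots come in primed pairs with
    equal values.  Column ranges of the returned template are the per-slot
    maxima, so every structure aligns to the template.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty helix-map file")
    header = lines[0].split("\t")
    if header[0] != "taxon":
        raise FormatError(f"{path}: first header field must be 'taxon'")
    slot_ids = header[1:]
    if not slot_ids:
        raise FormatError(f"{path}: no slot columns")
    for sid in slot_ids:
        parse_slot_id(sid)
    lengths_by_taxon = {}
    problems = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            problems.append(f"line {lineno}: expected {len(header)} fields, got {len(cells)}")
            continue
        taxon = cells[0]
        if taxon in lengths_by_taxon:
            problems.append(f"line {lineno}: duplicate taxon {taxon!r}")
            continue
        try:
            vals = {sid: int(c) for sid, c in zip(slot_ids, cells[1:])}
        except ValueError:
            problems.append(f"line {lineno}: non-integer cell")
            continue
        if any(v < 0 for v in vals.values()):
            problems.append(f"line {lineno}: negative length")
            continue
        lengths_by_taxon[taxon] = vals
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))
    if not lengths_by_taxon:
        raise FormatError(f"{path}: no taxon rows")
    template = _template_from_lengths(slot_ids, lengths_by_taxon)
    structures = [
        _canonical_structure(taxon, template, vals)
        for taxon, vals in lengths_by_taxon.items()
    ]
    return template, structures


def write_structural_alignment(slot_ids, lengths_by_taxon, path) -> None:
    """Write the helix-map TSV dialect read by :func:`load_structural_alignment`."""
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(slot_ids) + "\n")
        for taxon, vals in lengths_by_taxon.items():
            fh.write(taxon + "\t" + "\t".join(str(vals[s]) for s in slot_ids) + "\n")


def slot_lengths(template: HomologyTemplate, structure: SecondaryStructure) -> dict:
    """Per-slot segment lengths of a template-aligned structure."""
    out = {}
    for sub in _decompose_with_template(structure, template):
        out[sub.id] = sub.length
        if sub.kind == "S":
            out[template.slot(sub.id).partner] = sub.length
    return out


def write_character_matrix(matrix, path) -> None:
    """NEXUS export of a character matrix (see :mod:`ribophylo.nexus`)."""
    from .nexus import write_character_matrix as _write

    _write(matrix, path)
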