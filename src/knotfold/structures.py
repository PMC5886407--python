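"""Sequence and secondary-structure containers plus format I/O.

An RNA secondary structure is a set of base pairs i.j drawn on the backbone
as arcs; two arcs i.j and k.l *cross* when i < k < j < l.  Structures with
crossing arcs are pseudoknotted.  Internally everything is 0-based; the text
formats (dot-bracket, CT, BPSEQ) follow their 1-based conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

UNPAIRED = -1

#: bracket layers usable in dot-bracket strings, outermost dialect first
BRACKET_LAYERS: list[tuple[str, str]] = (
    [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
    + [(chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)]
)

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

_VALID_BASES = frozenset("ACGU")


class StructureError(ValueError):
    """Malformed structure or structure/sequence mismatch."""


class FormatError(ValueError):
    """Malformed structure file (dot-bracket, CT or BPSEQ)."""


def normalize_bases(raw: str) -> str:
    """Uppercase, map T->U, reject anything outside A/C/G/U."""
    bases = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(bases):
        if ch not in _VALID_BASES:
            raise StructureError(
                f"invalid base {ch!r} at position {pos + 1} (expected A/C/G/U/T)"
            )
    return bases


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over A/C/G/U with an identifier."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize_bases(self.bases))
        if len(self.bases) < 1:
            raise StructureError("empty sequence")

    @property
    def n(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i: int) -> str:
        return self.bases[i]


class PairTable:
    """Base-pairing state of a structure: partner index per position.

    ``table[i]`` is the 0-based partner of position ``i`` or :data:`UNPAIRED`.
    The table is an involution: ``table[i] == j`` implies ``table[j] == i``.
    """

    __slots__ = ("table",)

    def __init__(self, n_or_table: int | Iterable[int]) -> None:
        if isinstance(n_or_table, int):
            if n_or_table < 1:
                raise StructureError("structure length must be >= 1")
            self.table = [UNPAIRED] * n_or_table
        else:
            self.table = list(n_or_table)
            self._validate()

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple[int, int]]) -> "PairTable":
        pt = cls(n)
        for i, j in pairs:
            pt.add_pair(i, j)
        return pt

    def _validate(self) -> None:
        n = len(self.table)
        for i, j in enumerate(self.table):
            if j == UNPAIRED:
                continue
            if not (0 <= j < n):
                raise StructureError(f"partner {j} of position {i} out of range")
            if j == i:
                raise StructureError(f"position {i} paired with itself")
            if self.table[j] != i:
                raise StructureError(
                    f"pairing is not an involution at ({i}, {j}): "
                    f"partner of {j} is {self.table[j]}"
                )

    def add_pair(self, i: int, j: int) -> None:
        n = len(self.table)
        if not (0 <= i < n and 0 <= j < n):
            raise StructureError(f"pair ({i}, {j}) out of range for n={n}")
        if i == j:
            raise StructureError(f"position {i} cannot pair with itself")
        if self.table[i] != UNPAIRED or self.table[j] != UNPAIRED:
            raise StructureError(f"pair ({i}, {j}) conflicts with an existing pair")
        self.table[i] = j
        self.table[j] = i

    @property
    def n(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def __getitem__(self, i: int) -> int:
        return self.table[i]

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted list of pairs (i, j) with i < j, 0-based."""
        return [(i, j) for i, j in enumerate(self.table) if j > i]

    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.table) if j > i)

    def copy(self) -> "PairTable":
        pt = PairTable(len(self.table))
        pt.table = list(self.table)
        return pt

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairTable) and self.table == other.table

    def __hash__(self) -> int:
        return hash(tuple(self.table))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PairTable({write_dotbracket(self)!r})"


@dataclass
class StructureRecord:
    """A sequence together with one reference structure."""

    sequence: RnaSequence
    structure: PairTable
    source: str = "dot-bracket"

    def __post_init__(self) -> None:
        if self.sequence.n != self.structure.n:
            raise StructureError(
                f"sequence length {self.sequence.n} != structure length "
                f"{self.structure.n}"
            )


# ---------------------------------------------------------------------------
# crossing detection

def crossing_pairs(structure: PairTable) -> set[tuple[tuple[int, int], tuple[int, int]]]:
    """All pairs of arcs that cross: ((i,j),(k,l)) with i < k < j < l."""
    arcs = structure.pairs()
    out = set()
    for a in range(len(arcs)):
        i, j = arcs[a]
        for b in range(a + 1, len(arcs)):
            k, l = arcs[b]
            if i < k < j < l:
                out.add(((i, j), (k, l)))
    return out


def is_pseudoknotted(structure: PairTable) -> bool:
    arcs = structure.pairs()
    # sweep with a stack: a close that does not match the innermost open crosses
    stack: list[int] = []
    partner = structure.table
    for pos in range(len(partner)):
        j = partner[pos]
        if j == UNPAIRED:
            continue
        if j > pos:
            stack.append(pos)
        else:
            if stack and stack[-1] == j:
                stack.pop()
            else:
                return True
    return False if arcs else False


# ---------------------------------------------------------------------------
# dot-bracket

def parse_dotbracket(text: str) -> PairTable:
    """Parse a (possibly multi-layer) dot-bracket string into a PairTable.

    '.' marks unpaired; each bracket layer is matched independently, which is
    what lets crossing arcs be written down at all.
    """
    text = text.strip()
    if not text:
        raise FormatError("empty dot-bracket string")
    opens = {o: k for k, (o, _) in enumerate(BRACKET_LAYERS)}
    closes = {c: k for k, (_, c) in enumerate(BRACKET_LAYERS)}
    stacks: dict[int, list[int]] = {}
    pt = PairTable(len(text))
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in opens:
            stacks.setdefault(opens[ch], []).append(pos)
        elif ch in closes:
            layer = closes[ch]
            st = stacks.get(layer)
            if not st:
                o, c = BRACKET_LAYERS[layer]
                raise FormatError(
                    f"unbalanced {c!r} at column {pos + 1}: no open {o!r}"
                )
            pt.add_pair(st.pop(), pos)
        else:
            raise FormatError(f"unknown character {ch!r} at column {pos + 1}")
    for layer, st in stacks.items():
        if st:
            o, _ = BRACKET_LAYERS[layer]
            raise FormatError(
                f"unbalanced {o!r} opened at column {st[-1] + 1} never closed"
            )
    return pt


def assign_pages(structure: PairTable) -> dict[tuple[int, int], int]:
    """Greedy page (bracket-layer) assignment.

    Pairs are scanned by left endpoint; each goes to the lowest layer where it
    crosses no pair already on that layer.  Every resulting layer is on its
    own pseudoknot-free.
    """
    layers: list[list[tuple[int, int]]] = []
    assignment: dict[tuple[int, int], int] = {}
    for i, j in structure.pairs():
        placed = False
        for k, layer in enumerate(layers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                layer.append((i, j))
                assignment[(i, j)] = k
                placed = True
                break
        if not placed:
            layers.append([(i, j)])
            assignment[(i, j)] = len(layers) - 1
    return assignment


def write_dotbracket(structure: PairTable) -> str:
    """Render a PairTable as dot-bracket text using greedy page assignment."""
    assignment = assign_pages(structure)
    n_layers = max(assignment.values(), default=-1) + 1
    if n_layers > len(BRACKET_LAYERS):
        raise StructureError(
            f"structure needs {n_layers} bracket layers; only "
            f"{len(BRACKET_LAYERS)} are supported"
        )
    out = ["."] * len(structure)
    for (i, j), k in assignment.items():
        o, c = BRACKET_LAYERS[k]
        out[i] = o
        out[j] = c
    return "".join(out)


# ---------------------------------------------------------------------------
# dot-bracket files (3 lines: >id / sequence / structure)

def read_dotbracket_file(text: str) -> StructureRecord:
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith(">"):
        raise FormatError(
            "dot-bracket file must be: '>' header, sequence line, structure line"
        )
    seq = RnaSequence(lines[0][1:].strip() or "unnamed", lines[1])
    pt = parse_dotbracket(lines[2])
    if pt.n != seq.n:
        raise FormatError(
            f"sequence length {seq.n} != structure length {pt.n}"
        )
    return StructureRecord(seq, pt, source="dot-bracket")


def write_dotbracket_file(record: StructureRecord) -> str:
    return (
        f">{record.sequence.id}\n{record.sequence.bases}\n"
        f"{write_dotbracket(record.structure)}\n"
    )


# ---------------------------------------------------------------------------
# CT

def read_ct(text: str) -> StructureRecord:
    """Read a connect-table (CT) record: header with length, then one line
    per base: index, base, prev, next, partner, index."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"CT header must start with the length: {lines[0]!r}") from exc
    seq_id = " ".join(head[1:]) or "unnamed"
    if len(lines) - 1 != n:
        raise FormatError(f"CT header says {n} bases but file has {len(lines) - 1} rows")
    bases = []
    partners = [UNPAIRED] * n
    for lineno, ln in enumerate(lines[1:], start=2):
        f = ln.split()
        if len(f) < 6:
            raise FormatError(f"CT line {lineno}: expected 6 columns, got {len(f)}")
        idx = int(f[0])
        if idx != lineno - 1:
            raise FormatError(f"CT line {lineno}: index {idx} out of order")
        bases.append(f[1])
        p = int(f[4])
        if p:
            partners[idx - 1] = p - 1
    _check_partner_symmetry(partners, "CT")
    seq = RnaSequence(seq_id, "".join(bases))
    return StructureRecord(seq, PairTable(partners), source="CT")


def write_ct(record: StructureRecord) -> str:
    seq, pt = record.sequence, record.structure
    lines = [f"{seq.n} {seq.id}"]
    for i in range(seq.n):
        partner = pt[i] + 1 if pt[i] != UNPAIRED else 0
        nxt = i + 2 if i + 1 < seq.n else 0
        lines.append(f"{i + 1} {seq[i]} {i} {nxt} {partner} {i + 1}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BPSEQ

def read_bpseq(text: str) -> StructureRecord:
    """Read a BPSEQ record: one line per base: index, base, partner (0 = none)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError("empty BPSEQ file")
    n = len(lines)
    bases = []
    partners = [UNPAIRED] * n
    for lineno, ln in enumerate(lines, start=1):
        f = ln.split()
        if len(f) != 3:
            raise FormatError(f"BPSEQ line {lineno}: expected 3 columns, got {len(f)}")
        idx = int(f[0])
        if idx != lineno:
            raise FormatError(f"BPSEQ line {lineno}: index {idx} out of order")
        bases.append(f[1])
        p = int(f[2])
        if p:
            partners[idx - 1] = p - 1
    _check_partner_symmetry(partners, "BPSEQ")
    seq = RnaSequence("unnamed", "".join(bases))
    return StructureRecord(seq, PairTable(partners), source="BPSEQ")


def write_bpseq(record: StructureRecord) -> str:
    seq, pt = record.sequence, record.structure
    lines = []
    for i in range(seq.n):
        partner = pt[i] + 1 if pt[i] != UNPAIRED else 0
        lines.append(f"{i + 1} {seq[i]} {partner}")
    return "\n".join(lines) + "\n"


def _check_partner_symmetry(partners: list[int], fmt: str) -> None:
    for i, j in enumerate(partners):
        if j == UNPAIRED:
            continue
        if not (0 <= j < len(partners)):
            raise FormatError(
                f"{fmt} line {i + 1}: partner {j + 1} out of range"
            )
        if partners[j] != i:
            raise FormatError(
                f"{fmt} partner columns disagree: line {i + 1} says "
                f"{j + 1}, line {j + 1} says {partners[j] + 1}"
            )


# ---------------------------------------------------------------------------
# FASTA (sequences only)

def read_fasta(text: str) -> list[RnaSequence]:
    from io import StringIO

    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        out.append(RnaSequence(rec.id, str(rec.seq)))
    if not out:
        raise FormatError("no FASTA records found")
    return out


def write_fasta(seqs: Iterable[RnaSequence]) -> str:
    return "".join(f">{s.id}\n{s.bases}\n" for s in seqs)


def is_canonical(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def check_canonical(seq: RnaSequence, structure: PairTable) -> None:
    """Raise unless every pair is one of AU/UA/CG/GC/GU/UG."""
    if seq.n != structure.n:
        raise StructureError(
            f"sequence length {seq.n} != structure length {structure.n}"
        )
    for i, j in structure.pairs():
        if not is_canonical(seq[i], seq[j]):
            raise StructureError(
                f"non-canonical pair {seq[i]}{i + 1}.{seq[j]}{j + 1}"
            )
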