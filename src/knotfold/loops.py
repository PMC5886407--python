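"""Loop decomposition of (possibly pseudoknotted) secondary structures.

The energy of a structure in a loop-additive model is the sum of the energies
of its loops, so every base pair and every unpaired base must be charged to
exactly one loop.  For nested structures this is the classical hairpin /
stacked-pair / internal-loop / multiloop / exterior decomposition.  Crossing
pairs are organised into *bands* (consecutive, mutually nested pairs that
cross the same partners); bands that cross one another close a *pseudoloop*,
which is priced with an initiation term, a per-band term, a per-unpaired-base
term and a per-closed-subregion term.  Loops whose two closing pairs are
members of the same band "span the band" and get discounted variants of the
ordinary stacked-pair / internal-loop / multiloop energies.

The precise loop taxonomy in pseudoknotted context varies between models;
the conventions implemented here are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structures import (
    PairTable,
    RnaSequence,
    StructureError,
    check_canonical,
)

# loop kinds
HAIRPIN = "HAIRPIN"
STACK = "STACK"
INTERNAL = "INTERNAL"
MULTILOOP = "MULTILOOP"
EXTERIOR = "EXTERIOR"
PSEUDOLOOP = "PSEUDOLOOP"

# loop contexts
ORDINARY = "ORDINARY"
SPANS_BAND = "SPANS_BAND"
IN_MULTILOOP = "IN_MULTILOOP"
IN_PSEUDOLOOP = "IN_PSEUDOLOOP"
EXTERIOR_CTX = "EXTERIOR_CTX"

MIN_HAIRPIN_UNPAIRED = 3


class DecompositionError(StructureError):
    """Structure cannot be decomposed under the model's conventions."""


@dataclass(frozen=True)
class Band:
    """A maximal chain of consecutive, mutually nested crossing pairs that
    all cross the same set of non-member pairs."""

    members: tuple[tuple[int, int], ...]

    @property
    def outer(self) -> tuple[int, int]:
        return self.members[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.members[-1]

    def occupied(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two backbone intervals [i, i'] and [j', j] covered by the band."""
        (i, j), (i2, j2) = self.outer, self.inner
        return (i, i2), (j2, j)


@dataclass(frozen=True, slots=True)
class Loop:
    """One loop of the decomposition with the counts its energy depends on."""

    kind: str
    context: str
    closing_pairs: tuple[tuple[int, int], ...]
    unpaired_count: int = 0
    branch_count: int = 0
    closed_subregion_count: int = 0
    bands: tuple[Band, ...] = ()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "context": self.context,
            "closing_pairs": [list(p) for p in self.closing_pairs],
            "unpaired_count": self.unpaired_count,
            "branch_count": self.branch_count,
            "closed_subregion_count": self.closed_subregion_count,
            "bands": [[list(p) for p in b.members] for b in self.bands],
        }


@dataclass
class LoopDecomposition:
    loops: list[Loop]
    n: int

    def to_json_obj(self) -> dict:
        return {"n": self.n, "loops": [lp.to_dict() for lp in self.loops]}


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]


def find_bands(structure: PairTable) -> list[Band]:
    """Partition the crossing pairs of a structure into bands.

    Pairs are grouped when they cross exactly the same set of other pairs,
    then each group is split into maximal chains of nested pairs.  A
    pseudoknot-free structure has no crossing pairs and hence no bands.
    """
    arcs = structure.pairs()
    cross_sets: dict[tuple[int, int], frozenset] = {}
    for a in arcs:
        cs = frozenset(b for b in arcs if _crosses(a, b))
        if cs:
            cross_sets[a] = cs
    # group by identical cross set
    groups: dict[frozenset, list[tuple[int, int]]] = {}
    for a, cs in cross_sets.items():
        groups.setdefault(cs, []).append(a)
    bands: list[Band] = []
    for members in groups.values():
        members.sort()
        chain = [members[0]]
        for p in members[1:]:
            last = chain[-1]
            if last[0] < p[0] and p[1] < last[1]:  # nested inside previous
                chain.append(p)
            else:
                bands.append(Band(tuple(chain)))
                chain = [p]
        bands.append(Band(tuple(chain)))
    bands.sort(key=lambda b: b.outer)
    return bands


def _pseudoknot_components(bands: list[Band]) -> list[list[Band]]:
    """Group bands into connected components under the mutual-crossing
    relation; each component closes one pseudoloop."""
    k = len(bands)
    adj = [[] for _ in range(k)]
    for x in range(k):
        for y in range(x + 1, k):
            if any(
                _crosses(a, b) for a in bands[x].members for b in bands[y].members
            ):
                adj[x].append(y)
                adj[y].append(x)
    seen = [False] * k
    comps = []
    for s in range(k):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return [[bands[x] for x in comp] for comp in comps]


class _Node:
    """A node of the effective arc forest: a non-band pair or a whole
    pseudoknot component collapsed to its span."""

    __slots__ = ("start", "end", "pair", "comp", "children")

    def __init__(self, start, end, pair=None, comp=None):
        self.start = start
        self.end = end
        self.pair = pair        # (i, j) for a real non-band pair
        self.comp = comp        # list[Band] for a pseudoknot component
        self.children: list[_Node] = []


def decompose(seq: RnaSequence, structure: PairTable) -> LoopDecomposition:
    """Decompose a structure into the loops whose energies sum to its energy.

    Raises :class:`DecompositionError` for non-canonical pairs or hairpin
    loops shorter than the steric minimum of three unpaired bases.
    """
    check_canonical(seq, structure)
    n = structure.n
    bands = find_bands(structure)
    band_pairs = {p for b in bands for p in b.members}
    comps = _pseudoknot_components(bands)

    nodes = [
        _Node(p[0], p[1], pair=p)
        for p in structure.pairs()
        if p not in band_pairs
    ]
    for comp in comps:
        s = min(b.outer[0] for b in comp)
        e = max(b.outer[1] for b in comp)
        nodes.append(_Node(s, e, comp=comp))
    nodes.sort(key=lambda nd: (nd.start, -nd.end))

    # effective arcs never cross, so a stack builds the forest
    root = _Node(-1, n)
    stack = [root]
    for nd in nodes:
        while stack[-1].end < nd.end:
            stack.pop()
        stack[-1].children.append(nd)
        stack.append(nd)

    loops: list[Loop] = []

    def covered(kids: list[_Node]) -> int:
        return sum(k.end - k.start + 1 for k in kids)

    def process_pair(nd: _Node) -> None:
        i, j = nd.pair
        kids = nd.children
        u = (j - i - 1) - covered(kids)
        if not kids:
            if u < MIN_HAIRPIN_UNPAIRED:
                raise DecompositionError(
                    f"hairpin closed by ({i + 1}, {j + 1}) has only {u} "
                    f"unpaired bases (minimum {MIN_HAIRPIN_UNPAIRED})"
                )
            loops.append(Loop(HAIRPIN, ORDINARY, ((i, j),), unpaired_count=u))
            return
        if len(kids) == 1 and kids[0].pair is not None:
            inner = kids[0].pair
            if u == 0:
                loops.append(Loop(STACK, ORDINARY, ((i, j), inner)))
            else:
                loops.append(
                    Loop(INTERNAL, ORDINARY, ((i, j), inner), unpaired_count=u)
                )
            process_pair(kids[0])
            return
        # multiloop: >=2 branches, or a pseudoknot hanging directly inside
        loops.append(
            Loop(
                MULTILOOP,
                ORDINARY,
                ((i, j),),
                unpaired_count=u,
                branch_count=len(kids) + 1,
            )
        )
        for k in kids:
            if k.pair is not None:
                process_pair(k)
            else:
                process_pk(k, IN_MULTILOOP)

    def process_pk(nd: _Node, context: str) -> None:
        comp = nd.comp
        gaps: list[tuple[int, int, Band, int]] = []  # (lo, hi) exclusive gaps in bands
        for b in comp:
            ms = b.members
            for t in range(len(ms) - 1):
                (i1, j1), (i2, j2) = ms[t], ms[t + 1]
                gaps.append((i1, i2, b, t))
                gaps.append((j2, j1, b, t))

        def in_band_gap(k: _Node):
            for lo, hi, b, t in gaps:
                if lo < k.start and k.end < hi:
                    return (b, t)
            return None

        band_kids: dict[tuple[int, int], list[_Node]] = {}
        region_kids: list[_Node] = []
        for k in nd.children:
            hit = in_band_gap(k)
            if hit is None:
                region_kids.append(k)
            else:
                band_kids.setdefault((id(hit[0]), hit[1]), []).append(k)

        # unpaired bases of the pseudoloop itself: inside the span, outside
        # every band interval, not under a closed subregion
        occ = [False] * n
        for b in comp:
            for lo, hi in b.occupied():
                for x in range(lo, hi + 1):
                    occ[x] = True
        for k in nd.children:
            for x in range(k.start, k.end + 1):
                occ[x] = True
        u = sum(
            1
            for x in range(nd.start + 1, nd.end)
            if not occ[x] and structure[x] == -1
        )
        closed_subregions = [k for k in region_kids if k.pair is not None]
        nested_pks = [k for k in region_kids if k.comp is not None]
        loops.append(
            Loop(
                PSEUDOLOOP,
                context,
                tuple(b.outer for b in comp),
                unpaired_count=u,
                branch_count=len(comp),
                closed_subregion_count=len(closed_subregions),
                bands=tuple(comp),
            )
        )
        # loops between consecutive band members (they span the band)
        for b in comp:
            ms = b.members
            for t in range(len(ms) - 1):
                (i1, j1), (i2, j2) = ms[t], ms[t + 1]
                kids = band_kids.get((id(b), t), [])
                ub = (i2 - i1 - 1) + (j1 - j2 - 1) - covered(kids)
                if not kids:
                    if ub == 0:
                        loops.append(
                            Loop(STACK, SPANS_BAND, ((i1, j1), (i2, j2)))
                        )
                    else:
                        loops.append(
                            Loop(
                                INTERNAL,
                                SPANS_BAND,
                                ((i1, j1), (i2, j2)),
                                unpaired_count=ub,
                            )
                        )
                else:
                    loops.append(
                        Loop(
                            MULTILOOP,
                            SPANS_BAND,
                            ((i1, j1), (i2, j2)),
                            unpaired_count=ub,
                            branch_count=len(kids) + 2,
                        )
                    )
                    for k in kids:
                        if k.pair is not None:
                            process_pair(k)
                        else:
                            process_pk(k, IN_MULTILOOP)
        for k in closed_subregions:
            process_pair(k)
        for k in nested_pks:
            process_pk(k, IN_PSEUDOLOOP)

    ext_u = (root.end - root.start - 1) - covered(root.children)
    loops.append(
        Loop(
            EXTERIOR,
            EXTERIOR_CTX,
            (),
            unpaired_count=ext_u,
            branch_count=len(root.children),
        )
    )
    for k in root.children:
        if k.pair is not None:
            process_pair(k)
        else:
            process_pk(k, EXTERIOR_CTX)

    return LoopDecomposition(loops, n)
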