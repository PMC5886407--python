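"""Loop-additive free-energy model with pluggable parameter sets.

Two named parameter sets ship as packaged data:

* ``DP09`` — the pseudoknot parameters estimated for HotKnots V2.0;
* ``T99`` — the standard Turner-99-era multiloop terms combined with the
  Dirks–Pierce 2003 pseudoknot penalties.

Both were derived for 37 °C and 1 M NaCl; neither temperature nor salt is
configurable here.  The pseudoknot-free building blocks e_H, e_S and e_int
are opaque lookups backed by a compact nearest-neighbour table (see
docs/methods.md for the simplifications they carry).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

from .loops import (
    EXTERIOR,
    EXTERIOR_CTX,
    HAIRPIN,
    IN_MULTILOOP,
    IN_PSEUDOLOOP,
    INTERNAL,
    MULTILOOP,
    PSEUDOLOOP,
    SPANS_BAND,
    STACK,
    Loop,
    LoopDecomposition,
    decompose,
)
from .structures import PairTable, RnaSequence, StructureError, is_canonical

PARAM_SET_NAMES = ("DP09", "T99")

#: Jacobson–Stockmayer coefficient (1.75 RT at 310.15 K), kcal/mol
_JS_COEFF = 1.079
_MAX_TABLE_SIZE = 30
_ASYMMETRY_PENALTY = 0.5
_ASYMMETRY_CAP = 3.0


class EnergyError(StructureError):
    """Energy model cannot price the requested loop."""


def _read_data(name: str) -> str:
    return resources.files("knotfold.data").joinpath(name).read_text()


@dataclass(frozen=True)
class EnergyParams:
    """All scalar penalties of one parameter set plus the pk-free tables."""

    name: str
    P_s: float          # exterior pseudoloop initiation
    P_sm: float         # pseudoloop inside a multiloop
    P_sp: float         # pseudoloop inside a pseudoloop
    P_b: float          # per-band initiation
    P_up: float         # per unpaired base of a pseudoloop
    P_ps: float         # per closed subregion inside a pseudoloop
    stP_coeff: float    # multiplier on e_S for stacks that span a band
    intP_coeff: float   # multiplier on e_int for internal loops that span a band
    a: float            # ordinary multiloop initiation
    b: float            # ordinary multiloop per-branch
    c: float            # ordinary multiloop per-unpaired-base
    a2: float           # same three, for multiloops that span a band
    b2: float
    c2: float
    stack: dict[tuple[str, str], float]
    hairpin_init: dict[int, float]
    bulge_init: dict[int, float]
    internal_init: dict[int, float]

    # -- pk-free building blocks -------------------------------------------
    def e_S(self, seq: RnaSequence, i: int, j: int) -> float:
        """Energy of the stacked pair closed by i.j (inner pair i+1.j-1)."""
        return self._stack_term(seq[i], seq[j], seq[i + 1], seq[j - 1])

    def _stack_term(self, xo: str, yo: str, xi: str, yi: str) -> float:
        key = (xo + yo, xi + yi)
        try:
            return self.stack[key]
        except KeyError:
            raise EnergyError(f"no stacking energy for {key[0]}/{key[1]}") from None

    def e_H(self, seq: RnaSequence, i: int, j: int) -> float:
        """Energy of the hairpin loop closed by i.j."""
        size = j - i - 1
        return self._init(self.hairpin_init, size, lo=3)

    def e_int(self, seq: RnaSequence, i: int, d: int, e: int, j: int) -> float:
        """Energy of the internal loop / bulge closed by i.j with inner d.e."""
        n1, n2 = d - i - 1, j - e - 1
        if n1 < 0 or n2 < 0 or (n1 == 0 and n2 == 0):
            raise EnergyError(f"({i},{d},{e},{j}) does not delimit an internal loop")
        size = n1 + n2
        if n1 == 0 or n2 == 0:  # bulge
            g = self._init(self.bulge_init, size, lo=1)
            if size == 1:  # single-base bulges keep helix stacking
                g += self._stack_term(seq[i], seq[j], seq[d], seq[e])
            return g
        g = self._init(self.internal_init, size, lo=2)
        return g + min(_ASYMMETRY_CAP, _ASYMMETRY_PENALTY * abs(n1 - n2))

    @staticmethod
    def _init(table: dict[int, float], size: int, lo: int) -> float:
        if size < lo:
            raise EnergyError(f"loop size {size} below minimum {lo}")
        if size <= _MAX_TABLE_SIZE:
            return table[size]
        return table[_MAX_TABLE_SIZE] + _JS_COEFF * math.log(size / _MAX_TABLE_SIZE)

    def checksum(self) -> str:
        """Short digest of every scalar and table value, for report stamping."""
        h = hashlib.sha256()
        for field in (
            "P_s P_sm P_sp P_b P_up P_ps stP_coeff intP_coeff a b c a2 b2 c2"
        ).split():
            h.update(f"{field}={getattr(self, field)!r};".encode())
        for key in sorted(self.stack):
            h.update(f"{key}={self.stack[key]!r};".encode())
        for tab in (self.hairpin_init, self.bulge_init, self.internal_init):
            for k in sorted(tab):
                h.update(f"{k}={tab[k]!r};".encode())
        return h.hexdigest()[:12]


def load_params(name: str) -> EnergyParams:
    """Load one of the named parameter sets (``DP09`` or ``T99``)."""
    if name not in PARAM_SET_NAMES:
        raise EnergyError(
            f"unknown parameter set {name!r}; expected one of {PARAM_SET_NAMES}"
        )
    scalars: dict[str, float] = {}
    for line in _read_data(f"params_{name.lower()}.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, val = line.split("\t")
        scalars[key] = float(val)
    stack: dict[tuple[str, str], float] = {}
    for line in _read_data("stack.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        outer, inner, val = line.split("\t")
        stack[(outer, inner)] = float(val)
    hp: dict[int, float] = {}
    bu: dict[int, float] = {}
    il: dict[int, float] = {}
    for line in _read_data("loop_init.tsv").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("size"):
            continue
        size_s, h, b, i = line.split("\t")
        size = int(size_s)
        if h != "NA":
            hp[size] = float(h)
        bu[size] = float(b)
        if i != "NA":
            il[size] = float(i)
    return EnergyParams(
        name=name,
        stack=stack,
        hairpin_init=hp,
        bulge_init=bu,
        internal_init=il,
        **scalars,
    )


@dataclass
class EnergyBreakdown:
    """Total structure energy with one itemised contribution per loop."""

    total: float
    items: list[tuple[Loop, float]]

    def to_json_obj(self) -> dict:
        return {
            "total": self.total,
            "items": [
                {"loop": lp.to_dict(), "energy": e} for lp, e in self.items
            ],
        }


def loop_energy(loop: Loop, seq: RnaSequence, params: EnergyParams) -> float:
    """Free-energy contribution of one decomposed loop, kcal/mol."""
    kind, ctx = loop.kind, loop.context
    if kind == EXTERIOR:
        return 0.0
    if kind == HAIRPIN:
        i, j = loop.closing_pairs[0]
        return params.e_H(seq, i, j)
    if kind == STACK:
        i, j = loop.closing_pairs[0]
        e = params.e_S(seq, i, j)
        return params.stP_coeff * e if ctx == SPANS_BAND else e
    if kind == INTERNAL:
        (i, j), (d, e_) = loop.closing_pairs
        e = params.e_int(seq, i, d, e_, j)
        return params.intP_coeff * e if ctx == SPANS_BAND else e
    if kind == MULTILOOP:
        if ctx == SPANS_BAND:
            return (
                params.a2
                + params.b2 * loop.branch_count
                + params.c2 * loop.unpaired_count
            )
        return (
            params.a + params.b * loop.branch_count + params.c * loop.unpaired_count
        )
    if kind == PSEUDOLOOP:
        init = {
            EXTERIOR_CTX: params.P_s,
            IN_MULTILOOP: params.P_sm,
            IN_PSEUDOLOOP: params.P_sp,
        }[ctx]
        return (
            init
            + params.P_b * len(loop.bands)
            + params.P_up * loop.unpaired_count
            + params.P_ps * loop.closed_subregion_count
        )
    raise EnergyError(f"unknown loop kind {kind!r}")  # pragma: no cover


def pseudoloop_terms(loop: Loop, params: EnergyParams) -> dict[str, float]:
    """Split a pseudoloop's energy into its named components.

    Returns the initiation term (P_s, P_sm or P_sp according to context),
    the per-band term, the per-unpaired-base term and the per-closed-
    subregion term, plus the totals each contributes.  The sum of the
    ``*_total`` entries plus ``initiation`` equals :func:`loop_energy`.
    """
    if loop.kind != PSEUDOLOOP:
        raise EnergyError("pseudoloop_terms expects a PSEUDOLOOP loop")
    init = {
        EXTERIOR_CTX: params.P_s,
        IN_MULTILOOP: params.P_sm,
        IN_PSEUDOLOOP: params.P_sp,
    }[loop.context]
    return {
        "initiation": init,
        "per_band": params.P_b,
        "band_total": params.P_b * len(loop.bands),
        "per_unpaired": params.P_up,
        "unpaired_total": params.P_up * loop.unpaired_count,
        "per_subregion": params.P_ps,
        "subregion_total": params.P_ps * loop.closed_subregion_count,
    }


def evaluate_structure(
    seq: RnaSequence, structure: PairTable, params: EnergyParams
) -> EnergyBreakdown:
    """Energy of a structure as the sum over its loop decomposition."""
    deco = decompose(seq, structure)
    items = [(lp, loop_energy(lp, seq, params)) for lp in deco.loops]
    return EnergyBreakdown(total=sum(e for _, e in items), items=items)


def structure_energy(
    seq: RnaSequence, structure: PairTable, params: EnergyParams
) -> float:
    """Total energy only (same decomposition path as evaluate_structure)."""
    deco = decompose(seq, structure)
    return sum(loop_energy(lp, seq, params) for lp in deco.loops)
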