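"""Deterministic toy sequences and designed structures.

Everything here is seeded: the same seed reproduces the same record byte for
byte.  Designed fixtures use GC-dominated stems over A-rich linkers so that
the designed structure is the clear energy optimum, which is what makes the
brute-force oracle able to recover them; random sequences use a uniform base
composition.  Real RNA families are compositionally richer — see
docs/methods.md for what these fixtures do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import (
    PairTable,
    RnaSequence,
    StructureRecord,
    check_canonical,
    write_ct,
    write_fasta,
)

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}


class FixtureError(ValueError):
    """Requested fixture geometry is infeasible."""


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(n: int, seed: int, gc_bias: float = 0.5, id_: str = "") -> RnaSequence:
    """Random sequence; ``gc_bias`` is the total probability mass on G+C
    (split evenly), the default being a uniform base composition."""
    rng = _rng(seed)
    p = [gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2, (1 - gc_bias) / 2]
    bases = "".join(rng.choice(["G", "C", "A", "U"], size=n, p=p))
    return RnaSequence(id_ or f"random_n{n}_seed{seed}", bases)


def random_pair_table(n: int, seed: int, pair_prob: float = 0.35) -> PairTable:
    """A random matching on n positions (pseudoknots allowed); used for
    parser round-trip properties, so pairs need not be canonical."""
    rng = _rng(seed)
    pt = PairTable(n)
    free = list(range(n))
    while len(free) >= 2:
        i = free.pop(0)
        if rng.random() >= pair_prob:
            continue
        j = free.pop(int(rng.integers(len(free))))
        pt.add_pair(min(i, j), max(i, j))
    return pt


def _stem_bases(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    p = [gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2, (1 - gc_bias) / 2]
    return "".join(rng.choice(["G", "C", "A", "U"], size=length, p=p))


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def _linker(rng: np.random.Generator, length: int) -> str:
    # all-A so linkers do not seed competing helices
    return "A" * length


def make_hairpin(
    stem_len: int,
    loop_len: int,
    seed: int = 0,
    gc_bias: float = 0.9,
    verify: bool = False,
) -> StructureRecord:
    """A single designed hairpin: a GC-dominated stem around an A-rich loop."""
    if stem_len < 2:
        raise FixtureError("stem_len must be >= 2")
    if loop_len < 3:
        raise FixtureError("loop_len must be >= 3 (minimum hairpin size)")
    rng = _rng(seed)
    stem5 = _stem_bases(rng, stem_len, gc_bias)
    seq = RnaSequence(
        f"hairpin_s{stem_len}_l{loop_len}_seed{seed}",
        stem5 + _linker(rng, loop_len) + _revcomp(stem5),
    )
    n = seq.n
    pt = PairTable.from_pairs(n, [(t, n - 1 - t) for t in range(stem_len)])
    rec = StructureRecord(seq, pt, source="designed")
    check_canonical(seq, pt)
    if verify:
        _verify_designed(rec, allow_pseudoknots=False)
    return rec


def make_h_pseudoknot(
    stem1_len: int,
    stem2_len: int,
    spacer_lens: Sequence[int],
    seed: int = 0,
    gc_bias: float = 0.9,
    verify: bool = False,
) -> StructureRecord:
    """An H-type pseudoknot: two mutually crossing stems.

    Layout on the backbone: stem1-5' | g1 | stem2-5' | g2 | stem1-3' | g3 |
    stem2-3'; every stem1 pair crosses every stem2 pair, giving exactly two
    bands.  Both stems are GC-dominated so that the crossing stems pay for
    the pseudoloop penalties and the designed structure is the optimum.
    """
    if stem1_len < 2 or stem2_len < 2:
        raise FixtureError("both stems must have >= 2 pairs")
    g1, g2, g3 = spacer_lens
    if min(g1, g2, g3) < 0:
        raise FixtureError("spacers must be non-negative")
    # innermost spans: stem1 closes over g1+stem2_len+g2, stem2 over g2+stem1_len+g3
    if 1 + g1 + stem2_len + g2 < 4 or 1 + g2 + stem1_len + g3 < 4:
        raise FixtureError("spacers too short for the minimum hairpin spacing")
    rng = _rng(seed)
    s1 = _stem_bases(rng, stem1_len, gc_bias)
    s2 = _stem_bases(rng, stem2_len, gc_bias)
    bases = (
        s1
        + _linker(rng, g1)
        + s2
        + _linker(rng, g2)
        + _revcomp(s1)
        + _linker(rng, g3)
        + _revcomp(s2)
    )
    seq = RnaSequence(
        f"hpk_s{stem1_len}x{stem2_len}_g{g1}-{g2}-{g3}_seed{seed}", bases
    )
    a2 = stem1_len + g1
    b1 = a2 + stem2_len + g2
    b2 = b1 + stem1_len + g3
    pairs = [(t, b1 + stem1_len - 1 - t) for t in range(stem1_len)]
    pairs += [(a2 + t, b2 + stem2_len - 1 - t) for t in range(stem2_len)]
    pt = PairTable.from_pairs(seq.n, pairs)
    rec = StructureRecord(seq, pt, source="designed")
    check_canonical(seq, pt)
    if verify:
        _verify_designed(rec, allow_pseudoknots=True)
    return rec


def make_interleaved_chain(
    stem_len: int = 2,
    gap: int = 1,
    seed: int = 0,
    gc_bias: float = 0.9,
) -> StructureRecord:
    """A chain of four interleaved stems A, B, C, D where consecutive stems
    cross (A×B, B×C, C×D) — four bands closing a single pseudoloop."""
    if stem_len < 2:
        raise FixtureError("stem_len must be >= 2")
    rng = _rng(seed)
    halves = [_stem_bases(rng, stem_len, gc_bias) for _ in range(4)]
    # segment order: A5 B5 A3 C5 B3 D5 C3 D3
    order = [
        ("A", halves[0]),
        ("B", halves[1]),
        ("A'", _revcomp(halves[0])),
        ("C", halves[2]),
        ("B'", _revcomp(halves[1])),
        ("D", halves[3]),
        ("C'", _revcomp(halves[2])),
        ("D'", _revcomp(halves[3])),
    ]
    starts: dict[str, int] = {}
    bases = ""
    for k, (name, segment) in enumerate(order):
        starts[name] = len(bases)
        bases += segment
        if k < len(order) - 1:
            bases += _linker(rng, gap)
    seq = RnaSequence(f"chain4_s{stem_len}_g{gap}_seed{seed}", bases)
    pairs = []
    for name in "ABCD":
        s5, s3 = starts[name], starts[name + "'"]
        pairs += [(s5 + t, s3 + stem_len - 1 - t) for t in range(stem_len)]
    pt = PairTable.from_pairs(seq.n, pairs)
    rec = StructureRecord(seq, pt, source="designed")
    check_canonical(seq, pt)
    return rec


def make_multiloop_pseudoknot(seed: int = 0) -> StructureRecord:
    """An H-type pseudoknot embedded in a multiloop.

    A two-pair closing stem encloses a small hairpin branch and a complete
    H-type pseudoknot, so the loop directly containing the pseudoknot is a
    multiloop and the pseudoloop takes the in-multiloop initiation penalty.
    """
    inner = make_h_pseudoknot(2, 2, [2, 1, 3], seed=seed)
    hp = "GGGAAACCC"  # 3-pair hairpin branch
    bases = "CC" + "A" + hp + "A" + inner.sequence.bases + "A" + "GG"
    seq = RnaSequence(f"mlpk_seed{seed}", bases)
    n = seq.n
    off = 3 + len(hp) + 1  # offset of the embedded pseudoknot
    pairs = [(0, n - 1), (1, n - 2)]
    pairs += [(3, 11), (4, 10), (5, 9)]
    pairs += [(off + i, off + j) for i, j in inner.structure.pairs()]
    pt = PairTable.from_pairs(n, pairs)
    rec = StructureRecord(seq, pt, source="designed")
    check_canonical(seq, pt)
    return rec


def make_banded_internal_pseudoknot() -> StructureRecord:
    """A two-band pseudoknot whose first band contains a 1x1 internal loop
    between its two member pairs (an internal loop that spans a band)."""
    seq = RnaSequence("banded_internal", "GAGAGGACACAAACC")
    pairs = [(0, 9), (2, 7), (4, 14), (5, 13)]
    pt = PairTable.from_pairs(seq.n, pairs)
    rec = StructureRecord(seq, pt, source="designed")
    check_canonical(seq, pt)
    return rec


def make_overcrowded_input(seed: int = 3) -> tuple[StructureRecord, PairTable]:
    """An H-type fixture plus an overcrowded pseudoknot-free input structure.

    Two linker bases of the standard H-type fixture are changed so that a
    spurious pair (5, 9) nests inside stem 1 while crossing stem 2.  The
    returned input structure is stem 1 plus that pair: strict hierarchical
    folding must keep it (and pays for it), while relaxed hierarchical
    folding can drop it and reach the designed pseudoknot.
    """
    rec0 = make_h_pseudoknot(3, 3, [3, 1, 4], seed=seed)
    b = list(rec0.sequence.bases)
    b[5], b[9] = "G", "C"
    seq = RnaSequence(f"overcrowded_seed{seed}", "".join(b))
    rec = StructureRecord(seq, rec0.structure, source="designed")
    check_canonical(seq, rec.structure)
    G = PairTable.from_pairs(seq.n, [(0, 12), (1, 11), (2, 10), (5, 9)])
    return rec, G


def _verify_designed(rec: StructureRecord, allow_pseudoknots: bool) -> None:
    """Check that the brute-force oracle recovers the designed structure as
    the energy optimum (DP09).  Only feasible for small fixtures."""
    from .energy import load_params
    from .fold import brute_force_fold

    params = load_params("DP09")
    pred = brute_force_fold(
        rec.sequence, params, allow_pseudoknots=allow_pseudoknots, n_limit=rec.sequence.n
    )
    if pred.structure != rec.structure:
        raise FixtureError(
            f"designed fixture {rec.sequence.id} is not the energy optimum: "
            f"oracle found {pred.dotbracket}"
        )


@dataclass
class FixtureSpec:
    """One entry of a synthetic benchmark: which generator to call and how."""

    kind: str  # random | hairpin | h_pseudoknot | interleaved_chain
    seed: int = 0
    params: dict = field(default_factory=dict)

    def build(self) -> StructureRecord:
        if self.kind == "hairpin":
            return make_hairpin(seed=self.seed, **self.params)
        if self.kind == "h_pseudoknot":
            return make_h_pseudoknot(seed=self.seed, **self.params)
        if self.kind == "interleaved_chain":
            return make_interleaved_chain(seed=self.seed, **self.params)
        if self.kind == "random":
            p = dict(self.params)
            n = p.pop("n", 20)
            seq = random_sequence(n, self.seed, **p)
            return StructureRecord(seq, PairTable(n), source="random")
        raise FixtureError(f"unknown fixture kind {self.kind!r}")


def default_benchmark_specs() -> list[FixtureSpec]:
    """A small mixed battery used by the `simulate` subcommand and tests."""
    specs = [
        FixtureSpec("hairpin", seed=s, params={"stem_len": 4, "loop_len": 4})
        for s in range(3)
    ]
    specs += [
        FixtureSpec("hairpin", seed=s, params={"stem_len": 3, "loop_len": 5})
        for s in range(3, 5)
    ]
    specs += [
        FixtureSpec(
            "h_pseudoknot",
            seed=s,
            params={"stem1_len": 3, "stem2_len": 3, "spacer_lens": [3, 1, 4]},
        )
        for s in range(5, 8)
    ]
    specs += [
        FixtureSpec(
            "h_pseudoknot",
            seed=s,
            params={"stem1_len": 2, "stem2_len": 2, "spacer_lens": [2, 1, 3]},
        )
        for s in range(8, 10)
    ]
    return specs


def make_manifest(
    specs: Sequence[FixtureSpec], out_dir: str | Path
) -> Path:
    """Write FASTA + CT files plus a TSV manifest consumable by the
    benchmark runner.  Regeneration with the same specs and seeds is
    byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        rec = spec.build()
        rid = rec.sequence.id
        fasta_path = out / f"{rid}.fasta"
        ct_path = out / f"{rid}.ct"
        fasta_path.write_text(write_fasta([rec.sequence]))
        ct_path.write_text(write_ct(rec))
        rows.append((rid, fasta_path.name, ct_path.name, "CT"))
    manifest = out / "manifest.tsv"
    lines = ["id\tfasta\treference\tformat"]
    lines += ["\t".join(r) for r in rows]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
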