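"""Structure-prediction engines.

* :func:`mfe_pkfree` — Θ(n³) dynamic program for the pseudoknot-free minimum
  free-energy structure (divide-and-conquer over closing pair vs. split).
* :func:`brute_force_fold` — exhaustive enumeration oracle, optionally over
  pseudoknotted structures, for small n.
* :func:`hotspots` — the up-to-20 lowest-energy stems of a sequence.
* :func:`hierarchical_fold` — given a pseudoknot-free structure G, the
  minimum-energy structure G ∪ G′ whose added pairs G′ are themselves
  pseudoknot-free (the hierarchical-folding contract: G is kept).
* :func:`iterative_hfold` — relaxed hierarchical folding: refolds from the
  pseudoknot-free pages of intermediate results, so input pairs may be
  dropped when that lowers the energy.
* :func:`greedy_pk_fold` — hotspot seeding plus greedy addition of
  non-overlapping low-energy stems (heuristic, possibly pseudoknotted).

All engines break energy ties by preferring fewer pairs, then the
lexicographically smallest sorted pair list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .energy import EnergyBreakdown, EnergyParams, evaluate_structure
from .structures import (
    PairTable,
    RnaSequence,
    StructureError,
    assign_pages,
    is_canonical,
    is_pseudoknotted,
    write_dotbracket,
)

MIN_PAIR_SPAN = 4          # j - i >= 4 keeps hairpins at >= 3 unpaired bases
MAX_INTERNAL_LOOP = 30     # size cap on internal loops in the DP
_TIE_EPS = 1e-9

BRUTE_FORCE_LIMIT_PKFREE = 22
BRUTE_FORCE_LIMIT_PK = 18


@dataclass
class Stem:
    """A maximal run of >= 2 consecutively stacked canonical pairs."""

    pairs: tuple[tuple[int, int], ...]
    energy: float

    def positions(self) -> frozenset[int]:
        return frozenset(x for p in self.pairs for x in p)

    def as_pair_table(self, n: int) -> PairTable:
        return PairTable.from_pairs(n, self.pairs)


@dataclass
class Prediction:
    """A predicted structure, its energy and the itemised breakdown."""

    structure: PairTable
    energy: float
    breakdown: EnergyBreakdown
    provenance: dict = field(default_factory=dict)

    @property
    def dotbracket(self) -> str:
        return write_dotbracket(self.structure)


def _make_prediction(
    seq: RnaSequence,
    structure: PairTable,
    params: EnergyParams,
    engine: str,
    **extra,
) -> Prediction:
    bd = evaluate_structure(seq, structure, params)
    prov = {"engine": engine, "params": params.name, **extra}
    return Prediction(structure=structure, energy=bd.total, breakdown=bd, provenance=prov)


def _tie_key(energy: float, pairs: Sequence[tuple[int, int]]):
    return (energy, len(pairs), tuple(sorted(pairs)))


def _better(cand_key, best_key) -> bool:
    if best_key is None:
        return True
    if cand_key[0] < best_key[0] - _TIE_EPS:
        return True
    if cand_key[0] > best_key[0] + _TIE_EPS:
        return False
    return cand_key[1:] < best_key[1:]


def _can_pair(seq: RnaSequence, i: int, j: int) -> bool:
    return j - i >= MIN_PAIR_SPAN and is_canonical(seq[i], seq[j])


# ---------------------------------------------------------------------------
# pseudoknot-free MFE dynamic program

def mfe_pkfree(seq: RnaSequence, params: EnergyParams) -> Prediction:
    """Minimum free-energy pseudoknot-free structure.

    Standard loop-based recurrences: V(i,j) minimises over hairpin, stacked
    pair, internal loop (size-capped) and multiloop closings; WM handles
    multiloop fragments with the affine a + b·branches + c·unpaired score;
    W assembles the exterior loop.  Traceback is deterministic.
    """
    n = seq.n
    INF = math.inf
    if n < MIN_PAIR_SPAN + 1:
        return _make_prediction(seq, PairTable(n), params, "mfe")

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]

    def internal_candidates(i: int, j: int) -> Iterator[tuple[int, int]]:
        for d in range(i + 1, j - MIN_PAIR_SPAN):
            n1 = d - i - 1
            if n1 > MAX_INTERNAL_LOOP:
                break
            for e in range(j - 1, d + MIN_PAIR_SPAN - 1, -1):
                n2 = j - e - 1
                if n1 + n2 == 0:
                    continue  # that is the stack case
                if n1 + n2 > MAX_INTERNAL_LOOP:
                    break
                if _can_pair(seq, d, e):
                    yield d, e

    for span in range(MIN_PAIR_SPAN, n):
        for i in range(0, n - span):
            j = i + span
            if _can_pair(seq, i, j):
                best = params.e_H(seq, i, j)
                if _can_pair(seq, i + 1, j - 1):
                    v = params.e_S(seq, i, j) + V[i + 1][j - 1]
                    best = min(best, v)
                for d, e in internal_candidates(i, j):
                    v = params.e_int(seq, i, d, e, j) + V[d][e]
                    best = min(best, v)
                # multiloop: two WM fragments inside, + a + b for the closing
                for k in range(i + 2, j - 1):
                    left, right = WM[i + 1][k - 1], WM[k][j - 1]
                    if left < INF and right < INF:
                        v = params.a + params.b + left + right
                        best = min(best, v)
                V[i][j] = best
            # WM
            m = INF
            if V[i][j] < INF:
                m = V[i][j] + params.b
            if WM[i][j - 1] < INF:
                m = min(m, WM[i][j - 1] + params.c)
            if WM[i + 1][j] < INF:
                m = min(m, WM[i + 1][j] + params.c)
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] < INF and WM[k][j] < INF:
                    m = min(m, WM[i][k - 1] + WM[k][j])
            WM[i][j] = m
        # spans shorter than MIN_PAIR_SPAN never pair; WM stays INF there

    W = [0.0] * (n + 1)  # W[j] = best energy of prefix [0, j)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - MIN_PAIR_SPAN):
            if V[i][j - 1] < INF:
                best = min(best, W[i] + V[i][j - 1])
        W[j] = best

    pairs: list[tuple[int, int]] = []

    def close(x: float, y: float) -> bool:
        return abs(x - y) <= 1e-9

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        v = V[i][j]
        if close(v, params.e_H(seq, i, j)):
            return
        if _can_pair(seq, i + 1, j - 1) and close(
            v, params.e_S(seq, i, j) + V[i + 1][j - 1]
        ):
            trace_V(i + 1, j - 1)
            return
        for d, e in internal_candidates(i, j):
            if close(v, params.e_int(seq, i, d, e, j) + V[d][e]):
                trace_V(d, e)
                return
        for k in range(i + 2, j - 1):
            left, right = WM[i + 1][k - 1], WM[k][j - 1]
            if left < INF and right < INF and close(
                v, params.a + params.b + left + right
            ):
                trace_WM(i + 1, k - 1)
                trace_WM(k, j - 1)
                return
        raise AssertionError(f"traceback failed in V({i},{j})")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        m = WM[i][j]
        if WM[i][j - 1] < INF and close(m, WM[i][j - 1] + params.c):
            trace_WM(i, j - 1)
            return
        if WM[i + 1][j] < INF and close(m, WM[i + 1][j] + params.c):
            trace_WM(i + 1, j)
            return
        if V[i][j] < INF and close(m, V[i][j] + params.b):
            trace_V(i, j)
            return
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] < INF and WM[k][j] < INF and close(
                m, WM[i][k - 1] + WM[k][j]
            ):
                trace_WM(i, k - 1)
                trace_WM(k, j)
                return
        raise AssertionError(f"traceback failed in WM({i},{j})")  # pragma: no cover

    def trace_W(j: int) -> None:
        while j > 0:
            if close(W[j], W[j - 1]):  # prefer leaving j-1 unpaired on ties
                j -= 1
                continue
            for i in range(0, j - MIN_PAIR_SPAN):
                if V[i][j - 1] < INF and close(W[j], W[i] + V[i][j - 1]):
                    trace_V(i, j - 1)
                    j = i
                    break
            else:  # pragma: no cover
                raise AssertionError(f"traceback failed in W({j})")

    trace_W(n)
    structure = PairTable.from_pairs(n, pairs)
    return _make_prediction(seq, structure, params, "mfe")


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle

def enumerate_structures(
    seq: RnaSequence, allow_pseudoknots: bool
) -> Iterator[list[tuple[int, int]]]:
    """Yield every structure (as a sorted pair list) of canonical pairs with
    the minimum hairpin spacing, optionally restricted to pseudoknot-free."""
    n = seq.n
    cands: list[list[int]] = [
        [j for j in range(i + MIN_PAIR_SPAN, n) if is_canonical(seq[i], seq[j])]
        for i in range(n)
    ]
    used = [False] * n
    chosen: list[tuple[int, int]] = []

    def rec(pos: int) -> Iterator[list[tuple[int, int]]]:
        while pos < n and used[pos]:
            pos += 1
        if pos == n:
            yield list(chosen)
            return
        # pos unpaired
        used[pos] = True
        yield from rec(pos + 1)
        used[pos] = False
        for j in cands[pos]:
            if used[j]:
                continue
            if not allow_pseudoknots and any(
                a < pos < b < j or pos < a < j < b for a, b in chosen
            ):
                continue
            used[pos] = used[j] = True
            chosen.append((pos, j))
            yield from rec(pos + 1)
            chosen.pop()
            used[pos] = used[j] = False

    yield from rec(0)


def brute_force_fold(
    seq: RnaSequence,
    params: EnergyParams,
    allow_pseudoknots: bool = False,
    n_limit: Optional[int] = None,
) -> Prediction:
    """Global minimum over all enumerable structures — the verification
    oracle for the MFE hypothesis at toy scale.  Refuses long sequences."""
    if n_limit is None:
        n_limit = (
            BRUTE_FORCE_LIMIT_PK if allow_pseudoknots else BRUTE_FORCE_LIMIT_PKFREE
        )
    if seq.n > n_limit:
        raise ValueError(
            f"brute-force enumeration refused: n={seq.n} exceeds limit {n_limit}"
        )
    from .energy import structure_energy

    best_key = None
    best_pairs: list[tuple[int, int]] = []
    for pairs in enumerate_structures(seq, allow_pseudoknots):
        pt = PairTable.from_pairs(seq.n, pairs)
        e = structure_energy(seq, pt, params)
        key = _tie_key(e, pairs)
        if _better(key, best_key):
            best_key, best_pairs = key, pairs
    structure = PairTable.from_pairs(seq.n, best_pairs)
    return _make_prediction(
        seq, structure, params, "oracle", allow_pseudoknots=allow_pseudoknots
    )


# ---------------------------------------------------------------------------
# stems and hotspots

def enumerate_stems(seq: RnaSequence, params: EnergyParams) -> list[Stem]:
    """All maximal stems (runs of >= 2 stacked canonical pairs that leave
    room for a hairpin), scored as the sum of their stacking terms."""
    n = seq.n
    stems: list[Stem] = []
    for s in range(MIN_PAIR_SPAN, 2 * n - 3):  # s = i + j
        run: list[tuple[int, int]] = []
        i_lo = max(0, s - n + 1)
        i_hi = (s - MIN_PAIR_SPAN) // 2
        for i in range(i_lo, i_hi + 2):
            j = s - i
            ok = i <= i_hi and _can_pair(seq, i, j)
            if ok:
                run.append((i, j))
            else:
                if len(run) >= 2:
                    stems.append(_stem_from_run(seq, params, run))
                run = []
        if len(run) >= 2:
            stems.append(_stem_from_run(seq, params, run))
    stems.sort(key=lambda st: (st.energy, len(st.pairs), st.pairs))
    return stems


def _stem_from_run(
    seq: RnaSequence, params: EnergyParams, run: list[tuple[int, int]]
) -> Stem:
    e = sum(params.e_S(seq, i, j) for (i, j) in run[:-1])
    return Stem(pairs=tuple(run), energy=e)


def hotspots(seq: RnaSequence, params: EnergyParams, k: int = 20) -> list[Stem]:
    """Up to k lowest-energy stems, ascending by energy."""
    return enumerate_stems(seq, params)[:k]


# ---------------------------------------------------------------------------
# hierarchical folding

def _validate_hfold_input(seq: RnaSequence, G: PairTable) -> None:
    if G.n != seq.n:
        raise StructureError(
            f"input structure length {G.n} != sequence length {seq.n}"
        )
    if is_pseudoknotted(G):
        raise StructureError("hierarchical folding input must be pseudoknot-free")
    for i, j in G.pairs():
        if not is_canonical(seq[i], seq[j]):
            raise StructureError(
                f"non-canonical input pair {seq[i]}{i + 1}.{seq[j]}{j + 1}"
            )
        if j - i < MIN_PAIR_SPAN:
            raise StructureError(
                f"input pair ({i + 1},{j + 1}) violates the minimum hairpin spacing"
            )


def hierarchical_fold(
    seq: RnaSequence, G: PairTable, params: EnergyParams
) -> Prediction:
    """Minimum-energy structure G ∪ G′ over all pseudoknot-free G′ disjoint
    from G.  The input pairs are always contained in the output; G′ may
    cross G, which is how pseudoknots form under hierarchical folding."""
    _validate_hfold_input(seq, G)
    g_pairs = G.pairs()
    if not g_pairs:
        pred = mfe_pkfree(seq, params)
        pred.provenance = {
            "engine": "hfold",
            "params": params.name,
            "input": write_dotbracket(G),
        }
        return pred

    from .energy import structure_energy

    n = seq.n
    free = [G[i] == -1 for i in range(n)]
    cands = [
        (i, j)
        for i in range(n)
        if free[i]
        for j in range(i + MIN_PAIR_SPAN, n)
        if free[j] and is_canonical(seq[i], seq[j])
    ]

    best_key = None
    best_added: list[tuple[int, int]] = []
    chosen: list[tuple[int, int]] = []
    used = [False] * n

    def evaluate_current() -> None:
        nonlocal best_key, best_added
        pairs = g_pairs + chosen
        pt = PairTable.from_pairs(n, pairs)
        e = structure_energy(seq, pt, params)
        key = _tie_key(e, pairs)
        if _better(key, best_key):
            best_key, best_added = key, list(chosen)

    def rec(idx: int) -> None:
        evaluate_current()
        for t in range(idx, len(cands)):
            i, j = cands[t]
            if used[i] or used[j]:
                continue
            if any(a < i < b < j or i < a < j < b for a, b in chosen):
                continue  # added layer must itself stay pseudoknot-free
            used[i] = used[j] = True
            chosen.append((i, j))
            rec(t + 1)
            chosen.pop()
            used[i] = used[j] = False

    rec(0)
    structure = PairTable.from_pairs(n, g_pairs + best_added)
    return _make_prediction(
        seq, structure, params, "hfold", input=write_dotbracket(G)
    )


def iterative_hfold(
    seq: RnaSequence,
    inputs: Optional[Sequence[PairTable]] = None,
    params: Optional[EnergyParams] = None,
    max_rounds: int = 10,
) -> Prediction:
    """Relaxed hierarchical folding.

    For each input structure, fold hierarchically, then repeatedly re-seed
    from the pseudoknot-free pages of the current result while the energy
    improves (at most ``max_rounds`` rounds per input).  The global best
    over all inputs and rounds is returned; unlike strict hierarchical
    folding, the output need not contain the input pairs.
    """
    if params is None:
        raise ValueError("params is required")
    if inputs is None:
        inputs = [st.as_pair_table(seq.n) for st in hotspots(seq, params)]
    if not inputs:
        inputs = [PairTable(seq.n)]

    best: Optional[Prediction] = None
    best_key = None

    def consider(pred: Prediction) -> bool:
        nonlocal best, best_key
        key = _tie_key(pred.energy, pred.structure.pairs())
        if _better(key, best_key):
            best, best_key = pred, key
            return True
        return False

    for G0 in inputs:
        current = hierarchical_fold(seq, G0, params)
        consider(current)
        seen = {G0, current.structure}
        for _ in range(max_rounds):
            pages = _pkfree_pages(current.structure)
            improved = None
            for page in pages:
                if page in seen:
                    continue
                seen.add(page)
                cand = hierarchical_fold(seq, page, params)
                if cand.energy < current.energy - _TIE_EPS and (
                    improved is None or cand.energy < improved.energy - _TIE_EPS
                ):
                    improved = cand
                consider(cand)
            if improved is None:
                break
            current = improved

    assert best is not None
    best.provenance = {"engine": "ihfold", "params": params.name}
    return best


def _pkfree_pages(structure: PairTable) -> list[PairTable]:
    """Split a structure into its greedy bracket-layer pages; each page is a
    pseudoknot-free structure on its own."""
    assignment = assign_pages(structure)
    n_layers = max(assignment.values(), default=-1) + 1
    pages = []
    for k in range(n_layers):
        pages.append(
            PairTable.from_pairs(
                structure.n, [p for p, layer in assignment.items() if layer == k]
            )
        )
    return pages


# ---------------------------------------------------------------------------
# greedy stem assembly

def greedy_pk_fold(
    seq: RnaSequence, params: EnergyParams, max_outputs: int = 20
) -> list[Prediction]:
    """Hotspot-seeded greedy assembly.

    Each of the up-to-20 hotspots seeds a structure; the best non-overlapping
    stem is added while the total energy keeps decreasing.  Outputs are
    deduplicated and sorted by energy; the first element is the engine's
    final answer.
    """
    from .energy import structure_energy

    stems = enumerate_stems(seq, params)
    seeds = stems[:max_outputs]
    if not seeds:
        return [_make_prediction(seq, PairTable(seq.n), params, "greedy")]

    results: dict[PairTable, Prediction] = {}
    for seed in seeds:
        current_pairs = set(seed.pairs)
        current_pos = set(x for p in seed.pairs for x in p)
        pt = PairTable.from_pairs(seq.n, current_pairs)
        current_e = structure_energy(seq, pt, params)
        while True:
            best_stem = None
            best_e = current_e
            for st in stems:
                if current_pos & set(x for p in st.pairs for x in p):
                    continue
                cand = PairTable.from_pairs(
                    seq.n, list(current_pairs) + list(st.pairs)
                )
                e = structure_energy(seq, cand, params)
                if e < best_e - _TIE_EPS:
                    best_e, best_stem = e, st
            if best_stem is None:
                break
            current_pairs.update(best_stem.pairs)
            current_pos.update(x for p in best_stem.pairs for x in p)
            current_e = best_e
        final = PairTable.from_pairs(seq.n, current_pairs)
        if final not in results:
            results[final] = _make_prediction(seq, final, params, "greedy")

    out = sorted(
        results.values(),
        key=lambda p: _tie_key(p.energy, p.structure.pairs()),
    )
    return out[:max_outputs]
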