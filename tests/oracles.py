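"""Independent brute-force oracles shared by the test suite."""

from knotfold.energy import structure_energy
from knotfold.fold import enumerate_structures
from knotfold.structures import PairTable, is_pseudoknotted


def constrained_hfold_oracle(seq, G, params):
    """Minimum energy over all structures that contain G and whose added
    pairs are, on their own, pseudoknot-free.  Enumerates everything."""
    g = set(G.pairs())
    best = None
    for pairs in enumerate_structures(seq, allow_pseudoknots=True):
        ps = set(pairs)
        if not g <= ps:
            continue
        added = PairTable.from_pairs(seq.n, ps - g)
        if is_pseudoknotted(added):
            continue
        e = structure_energy(seq, PairTable.from_pairs(seq.n, pairs), params)
        if best is None or e < best - 1e-9:
            best = e
    return best
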