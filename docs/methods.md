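# Methods

This note records the model conventions knotfold implements, the choices
made where the published descriptions leave room, and what the synthetic
fixtures do and do not establish.

## Energy model

Structure energy is strictly loop-additive: every base pair closes exactly
one loop, every unpaired base is charged to exactly one loop, and the total
is the sum of the per-loop terms. Two scalar parameter sets ship as data
(`DP09`, `T99`; kcal/mol at 37 °C, 1 M NaCl — neither temperature nor salt
is configurable):

| symbol | meaning | DP09 | T99 |
|--------|---------|------|-----|
| P_s  | exterior pseudoloop initiation | −1.38 | 9.6 |
| P_sm | pseudoloop inside a multiloop  | 10.07 | 15.00 |
| P_sp | pseudoloop inside a pseudoloop | 15.00 | 15.00 |
| P_b  | band initiation                | 2.46  | 0.2 |
| P_up | unpaired base in a pseudoloop  | 0.06  | 0.1 |
| P_ps | closed subregion in a pseudoloop | 0.96 | 0.1 |
| stP  | multiplier on e_S in a band    | 0.89  | 0.83 |
| intP | multiplier on e_int in a band  | 0.74  | 0.83 |
| a, b, c    | ordinary multiloop: initiation, per-branch, per-unpaired | 3.39, 0.03, 0.02 | 3.4, 0.4, 0 |
| a′, b′, c′ | multiloop spanning a band                                | 3.41, 0.56, 0.12 | 3.4, 0.4, 0 |

### Pseudoknot-free building blocks

The standard loops (e_H, e_S, e_int) are opaque lookups behind the
parameter object, backed by a compact nearest-neighbour table:

* **Stacks.** Watson–Crick/Watson–Crick stacking free energies use the
  standard 37 °C nearest-neighbour values (e.g. CG/CG −3.26, GC/CG −3.42,
  AU/AU −0.93). Stacks involving a G·U wobble carry a single flat value of
  −1.00 kcal/mol. This flattening loses the sequence dependence of wobble
  stacking; it does not affect any pseudoknot-specific term.
* **Hairpins.** Size-only initiation (5.4 at size 3 up to 6.4 at size 9),
  Jacobson–Stockmayer extrapolation `ΔG(m) = ΔG(30) + 1.079·ln(m/30)`
  beyond the table. No terminal mismatches, no sequence-special cases.
* **Internal loops and bulges.** Size-only initiation plus an asymmetry
  penalty `min(3.0, 0.5·|n1 − n2|)`; single-base bulges keep the stacking
  term of their closing pairs. No 1×1/1×2/2×2 tables, no mismatches.
* **No dangles, coaxial stacking or terminal-AU penalties** anywhere.

These simplifications make the pseudoknot terms — which are fully specified
scalars — exactly testable while keeping the pk-free part pluggable: the
evaluator only ever calls `e_H(i,j)`, `e_S(i,j)`, `e_int(i,d,e,j)`.
Absolute energies therefore differ from full Turner-model implementations;
all comparisons inside the package (DP vs oracle, engine vs engine) are
internally consistent because every path shares one evaluator. Energies are
carried at full float precision and rounded to two decimals only at display.

## Loop decomposition of pseudoknotted structures

The precise loop taxonomy in pseudoknotted context is model-dependent; the
conventions here are an interpretation, chosen to mirror the parameter
table's row descriptions, and are applied uniformly by the single
decomposition routine:

* **Bands.** Crossing pairs are grouped when they cross exactly the same
  set of other pairs; each group is split into maximal chains of mutually
  nested pairs. A band's two backbone intervals run from its outer to its
  inner pair on each side.
* **Pseudoloops.** Bands that (transitively) cross one another close one
  pseudoloop. Its unpaired bases are those inside the pseudoloop's span but
  outside every band interval and outside every closed subregion. A
  **closed subregion** (the P_ps counter) is a pseudoknot-free substructure
  whose outermost pair hangs directly on the pseudoloop, i.e. lies in the
  pseudoloop region without being a band member. A nested pseudoknot
  hanging directly on a pseudoloop is scored as its own pseudoloop with the
  P_sp initiation and is not counted in P_ps.
* **Context rule.** A pseudoloop directly inside the exterior loop takes
  P_s; directly inside a multiloop, P_sm; directly inside another
  pseudoloop's region, P_sp. A pseudoknot that is the *only* branch under a
  closing pair is treated as sitting in a (two-branch) multiloop — the
  model has no "internal-loop-containing-pseudoknot" term.
* **Spans-band loops.** The region between two consecutive members of one
  band is a stacked pair (adjacent members), an internal loop (unpaired
  bases only) or a multiloop that spans the band (if it has branches); they
  are scored with the discounted/primed coefficients. A multiloop that
  spans a band counts both band members among its branches.
* **Branch counting.** Ordinary multiloops count their closing pair plus
  each child branch (so a two-child multiloop has 3 branches), matching the
  affine form `a + b·branches + c·unpaired`.
* **Minimum hairpin.** Three unpaired bases (pair span ≥ 4 everywhere);
  the decomposition refuses shorter hairpins, and all engines respect the
  constraint.

The decomposition is deterministic (loops emitted outer-to-inner,
left-to-right), handles arbitrary crossing structures (not only the
density-2 class the hierarchical engines search), and is validated against
an independently written recursive decomposition on pseudoknot-free
structures.

## Folding engines

* **`mfe_pkfree`** — standard Θ(n³) loop-based recurrences (V/WM/W
  matrices) with internal loops capped at 30 unpaired bases, the usual
  dynamic-programming practice; at the oracle-comparison sizes the cap is
  never active. Traceback is deterministic.
* **`brute_force_fold`** — enumerates every structure over canonical pairs
  with the minimum hairpin spacing (backtracking over a per-position
  candidate list), optionally restricted to non-crossing structures, and
  evaluates each with the same evaluator. It refuses sequences beyond its
  limits (22 nt pseudoknot-free, 18 nt with pseudoknots by default) rather
  than truncating. This is the ground truth the other engines are tested
  against.
* **`hotspots` / stems** — a stem is a maximal run of ≥ 2 consecutively
  stacked canonical pairs that leaves room for a hairpin; its score is the
  sum of its stacking terms only. Hotspots are the up-to-20 lowest-energy
  stems, ties broken by pair count then pair list.
* **`hierarchical_fold`** — given a pseudoknot-free G, searches all
  pseudoknot-free G′ over the positions G leaves free (G′ may cross G) and
  returns the minimum-energy G ∪ G′. The search is exhaustive over that
  constrained space — the contract, not the published recurrences, is what
  is implemented — so it is exact but exponential in the worst case and
  intended for the toy scale of this package (tens of nucleotides). With
  G = ∅ it delegates to the pseudoknot-free DP.
* **`iterative_hfold`** — relaxed hierarchical folding, an interpretation
  of the published scheme: for each input structure, fold hierarchically,
  split the result into its greedy bracket-layer pages (each page is
  pseudoknot-free alone), re-seed from any unseen page, and repeat while
  the energy improves, up to 10 rounds per input; the global best over all
  inputs and rounds is returned. By default the inputs are the hotspots as
  single-stem structures, and the final answer is the lowest-energy
  prediction over all of them. Because re-seeding abandons the original
  input, pairs of an overcrowded input can be dropped — the behaviour the
  strict engine cannot show.
* **`greedy_pk_fold`** — each hotspot seeds a structure; the best
  energy-decreasing non-overlapping stem is added until no addition helps;
  up to 20 deduplicated outputs sorted by energy.

Everywhere, energy ties are broken by fewer pairs, then the
lexicographically smallest sorted pair list, so results are reproducible.
The density-2 class restriction of the hierarchical engines' namesakes is
not enforced as an explicit filter; the searched space (G and G′ each
pseudoknot-free) is used directly.

## Accuracy and statistics

* Sensitivity = correct/|reference|, PPV = correct/|predicted|, F-measure =
  their harmonic mean; a pair is correct only on exact index match; any
  zero denominator sets the value (and F) to 0.
* Bootstrap: 95% percentile interval of the resampled mean, 10 000
  replicates by default (the replicate count is a package choice), seeded.
  Percentile intervals at n ≈ 50 genuinely cover slightly under the nominal
  95% (≈ 94% in the package's own simulation) — a known property of the
  percentile method, not a bug.
* Permutation test: two-sided on the difference of means (the statistic is
  a package choice), exact enumeration when the number of relabelings is at
  most 20 000, otherwise Monte Carlo with p = (b+1)/(m+1); unpaired by
  design; no multiple-testing correction is applied to pairwise
  comparisons.
* Length bins [10,50), [50,100), [100,150), [150,400]; records outside the
  range are excluded with a warning; empty bins are absent, not zero.
* The benchmark runner records each prediction's energy alongside its
  F-measure, so energy rank versus accuracy rank can be inspected — the
  package reports it and deliberately asserts nothing about it.

## Synthetic fixtures

Fixtures are fully seeded and generated at run time: GC-dominated stems
(90% G+C by default) over all-A linkers make the designed structure the
clear optimum, which the brute-force oracle verifies (`verify=True`).
Geometries: hairpins, H-type pseudoknots (two crossing stems, two bands),
a chain of four interleaved stems (four bands, one pseudoloop), an H-type
pseudoknot embedded in a multiloop, a band containing an internal loop, and
an "overcrowded input" variant where two linker bases are changed so a
spurious nested pair exists that blocks the crossing stem. Random
sequences use a uniform base composition.

What these fixtures do **not** emulate: the base composition, length
distribution and structural diversity of real RNA families; non-canonical
annotations in curated references; long-range pseudoknots. Passing tests
establish the internal correctness of the decomposition, evaluator and
engines — not prediction accuracy on biological RNA. The benchmark
manifest format (TSV of id, FASTA path, reference path, format) accepts
curated datasets for that purpose, but none are bundled.

## Problem sizes

The verification batteries are sized for exactness: the enumeration oracle
runs at ≤ 22 nt (pseudoknot-free) and ≤ 18 nt (pseudoknotted), where the
complete structure space is a few thousand to a few hundred thousand
candidates; the MFE-vs-oracle battery uses 50 random sequences per
parameter set and the hierarchical-vs-constrained-oracle battery 25
designed fixtures. These are the package's chosen study conditions.

## Known limitations

* The pk-free nearest-neighbour tables are deliberately compact (flat
  wobble stacking, size-only loop initiations); absolute energies are not
  comparable to full Turner-model implementations.
* The exact functional form of the pseudoloop term (what P_ps counts, and
  how pseudoloops interact with nested multiloops) follows the row
  descriptions of the parameter table; other implementations resolve the
  ambiguity differently.
* `hierarchical_fold` is exact but exponential; it is an oracle-grade
  reference for short sequences, not an O(n³) production implementation.
* Exterior-loop bases and helix ends carry no terms, so very short helices
  are penalised only through loop initiations.
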