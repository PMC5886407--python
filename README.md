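# knotfold

A toolkit for RNA secondary structures **with pseudoknots**: a loop-additive
energy model with the DP09 and T99 pseudoknot parameter sets, loop/band
decomposition of crossing structures, pseudoknot-free minimum-free-energy
(MFE) folding, hotspot-based heuristic folding, hierarchical and relaxed
("iterative") hierarchical folding, a brute-force enumeration oracle, and
the accuracy/statistics machinery (sensitivity, PPV, F-measure, bootstrap
confidence intervals, permutation tests) used to compare structure
predictors on a common footing.

It is aimed at people studying *how* pseudoknotted structure prediction
methods differ — folding hypothesis versus energy model — at desk scale:
every fixture is generated programmatically, every engine shares one
evaluator, and exhaustive enumeration is available as ground truth for
small sequences.

## The model

A secondary structure *R* of sequence *S* is a set of base pairs *i.j*
(canonical pairs only: AU, UA, CG, GC, GU, UG). Pairs *i.j* and *k.l* with
*i < k < j < l* **cross**; structures with crossing pairs are pseudoknotted.
The free energy of *R* is the sum of the energies of its loops:

* hairpin, stacked pair, internal loop and exterior loop as in the classical
  nearest-neighbour model, with the ordinary multiloop scored affinely as
  `a + b·branches + c·unpaired`;
* crossing pairs are grouped into **bands** (consecutive, mutually nested
  pairs that cross the same partners); bands that cross one another close a
  **pseudoloop**, scored `P_x + P_b·(#bands) + P_up·(#unpaired) +
  P_ps·(#closed subregions)`, where the initiation `P_x` is `P_s`, `P_sm`
  or `P_sp` depending on whether the pseudoloop sits in the exterior loop,
  in a multiloop, or inside another pseudoloop;
* stacked pairs and internal loops whose closing pairs lie in the same band
  are discounted: `e_stP = 0.89·e_S` and `e_intP = 0.74·e_int` under DP09
  (both `0.83·` under T99); multiloops that span a band use the primed
  coefficients `a′, b′, c′`.

Both parameter sets (37 °C, 1 M NaCl) ship as packaged data; `DP09` is the
default, `T99` is the Turner-99-era alternative.

Folding engines, all over the same evaluator:

| engine   | idea                                                            |
|----------|-----------------------------------------------------------------|
| `mfe`    | Θ(n³) dynamic program, pseudoknot-free MFE                       |
| `oracle` | exhaustive enumeration (optionally pseudoknotted), small n only  |
| `hfold`  | hierarchical folding: keep a given pseudoknot-free structure G, add the best pseudoknot-free layer G′ (which may cross G) |
| `ihfold` | relaxed hierarchical folding: re-seed from the pages of intermediate results; may drop input pairs |
| `greedy` | hotspot stems + greedy addition of non-overlapping stems         |

## Worked example

Generate an H-type pseudoknot fixture (two crossing GC stems) and inspect
its energy:

```python
from knotfold.fixtures import make_h_pseudoknot
from knotfold.structures import write_fasta, write_ct
rec = make_h_pseudoknot(3, 3, [3, 1, 4], seed=5)
open("pk.fasta", "w").write(write_fasta([rec.sequence]))
open("pk.ct", "w").write(write_ct(rec))
```

```
$ knotfold energy pk.fasta pk.ct
kind        context       closing_pairs  unpaired  branches  energy
EXTERIOR    EXTERIOR_CTX                 0         1         0.00
PSEUDOLOOP  EXTERIOR_CTX  1.13;7.20      8         2         4.02
STACK       SPANS_BAND    1.13;2.12      0         0         -2.90
STACK       SPANS_BAND    2.12;3.11      0         0         -2.90
STACK       SPANS_BAND    7.20;8.19      0         0         -2.90
STACK       SPANS_BAND    8.19;9.18      0         0         -2.90
TOTAL                                                        -7.59
```

The pseudoloop item is the exterior initiation plus two band penalties plus
eight unpaired bases: −1.38 + 2·2.46 + 8·0.06 = 4.02 kcal/mol. Each stack
is the nearest-neighbour CG/CG value −3.26 discounted by 0.89 because it
spans a band. The greedy engine recovers the designed pseudoknot:

```
$ knotfold fold pk.fasta --engine greedy
id                      engine  energy  structure
hpk_s3x3_g3-1-4_seed5   greedy  -7.59   (((...[[[.)))....]]]
```

Benchmarks pair sequences with reference structures through a TSV manifest
(`knotfold simulate --out-dir fixtures/` writes one) and compare engines
with bootstrap CIs and permutation tests:

```
$ knotfold bench fixtures/manifest.tsv --engines mfe,greedy --seed 1
```

## Layout

* `knotfold.structures` — sequences, pair tables, dot-bracket/CT/BPSEQ/FASTA I/O
* `knotfold.loops` — band finding and loop decomposition
* `knotfold.energy` — parameter sets and the loop-additive evaluator
* `knotfold.fold` — the five folding engines
* `knotfold.evaluate` — metrics, statistics, benchmark runner
* `knotfold.fixtures` — seeded toy-structure generators and manifests
* `knotfold.cli` — the `knotfold` command

See `docs/methods.md` for the model conventions, their assumptions, and
known limitations.
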