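"""Accuracy metrics and the statistical machinery for comparing predictors.

Per-structure accuracy is base-pair sensitivity, positive predictive value
(PPV) and their harmonic mean, the F-measure; a predicted pair is correct
only on exact index match.  Method comparisons use bootstrap 95% percentile
confidence intervals of the mean F-measure and a two-sided permutation test
on the difference of mean F-measures.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .energy import EnergyParams
from .structures import (
    PairTable,
    RnaSequence,
    StructureError,
    read_bpseq,
    read_ct,
    read_dotbracket_file,
    read_fasta,
)

#: sequence-length bins used for length-stratified accuracy summaries
LENGTH_BINS: list[tuple[int, int, str]] = [
    (10, 50, "[10,50)"),
    (50, 100, "[50,100)"),
    (100, 150, "[100,150)"),
    (150, 400, "[150,400]"),
]

EXACT_PERMUTATION_LIMIT = 20_000


@dataclass
class EvalRecord:
    """Accuracy of one prediction against one reference structure."""

    id: str
    n: int
    sensitivity: float
    ppv: float
    fmeasure: float
    length_bin: Optional[str] = None
    energy: Optional[float] = None


def length_bin(n: int) -> Optional[str]:
    for lo, hi, label in LENGTH_BINS:
        if lo <= n < hi:
            return label
    if n == LENGTH_BINS[-1][1]:  # the last bin is closed: [150, 400]
        return LENGTH_BINS[-1][2]
    return None


def accuracy(
    reference: PairTable, predicted: PairTable, seq_id: str = ""
) -> EvalRecord:
    """Sensitivity, PPV and F-measure of a prediction.

    Sensitivity = correct / reference pairs; PPV = correct / predicted
    pairs; F = harmonic mean.  A zero denominator sets the corresponding
    value (and hence F) to 0.
    """
    if reference.n != predicted.n:
        raise StructureError(
            f"reference length {reference.n} != prediction length {predicted.n}"
        )
    ref = set(reference.pairs())
    pred = set(predicted.pairs())
    correct = len(ref & pred)
    sens = correct / len(ref) if ref else 0.0
    ppv = correct / len(pred) if pred else 0.0
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else 0.0
    return EvalRecord(
        id=seq_id,
        n=reference.n,
        sensitivity=sens,
        ppv=ppv,
        fmeasure=f,
        length_bin=length_bin(reference.n),
    )


def bootstrap_ci(
    values: Sequence[float],
    level: float = 0.95,
    replicates: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean of ``values``."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(replicates, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    seed: int = 0,
    n_resamples: int = 10_000,
) -> float:
    """Two-sided permutation test for a difference in means.

    Relabelings are enumerated exhaustively when there are at most
    :data:`EXACT_PERMUTATION_LIMIT` of them; otherwise a Monte-Carlo
    estimate p = (b + 1) / (m + 1) is used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    nx = xa.size
    obs = abs(xa.mean() - ya.mean())
    total = math.comb(pooled.size, nx)
    tol = 1e-12
    if total <= EXACT_PERMUTATION_LIMIT:
        vals = pooled.tolist()
        ny = pooled.size - nx
        s_all = sum(vals)
        hits = 0
        for combo in itertools.combinations(vals, nx):
            sx = sum(combo)
            if abs(sx / nx - (s_all - sx) / ny) >= obs - tol:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled.size)
        d = abs(pooled[perm[:nx]].mean() - pooled[perm[nx:]].mean())
        if d >= obs - tol:
            b += 1
    return (b + 1) / (n_resamples + 1)


def bin_by_length(records: Sequence[EvalRecord]) -> dict[str, float]:
    """Mean F-measure per length bin; empty bins are simply absent.
    Records outside [10, 400] are excluded with a warning."""
    groups: dict[str, list[float]] = {}
    for rec in records:
        label = rec.length_bin if rec.length_bin else length_bin(rec.n)
        if label is None:
            warnings.warn(
                f"record {rec.id!r} (n={rec.n}) outside the [10, 400] "
                "length range; excluded from the binned summary"
            )
            continue
        groups.setdefault(label, []).append(rec.fmeasure)
    order = [label for _, _, label in LENGTH_BINS]
    return {
        label: float(np.mean(groups[label])) for label in order if label in groups
    }


# ---------------------------------------------------------------------------
# benchmark runner

_READERS = {
    "CT": read_ct,
    "BPSEQ": read_bpseq,
    "dot-bracket": read_dotbracket_file,
}


def _engine_registry() -> dict[str, Callable]:
    from . import fold

    def run_hfold(seq: RnaSequence, params: EnergyParams):
        hs = fold.hotspots(seq, params, k=1)
        G = hs[0].as_pair_table(seq.n) if hs else PairTable(seq.n)
        return fold.hierarchical_fold(seq, G, params)

    return {
        "mfe": lambda s, p: fold.mfe_pkfree(s, p),
        "oracle": lambda s, p: fold.brute_force_fold(s, p, allow_pseudoknots=True),
        "hfold": run_hfold,
        "ihfold": lambda s, p: fold.iterative_hfold(s, params=p),
        "greedy": lambda s, p: fold.greedy_pk_fold(s, p)[0],
    }


ENGINE_NAMES = ("mfe", "oracle", "hfold", "ihfold", "greedy")


@dataclass
class BenchmarkReport:
    """Everything the accuracy comparison protocol produces for one run."""

    engines: list[str]
    records: dict[str, list[EvalRecord]]
    mean_f: dict[str, float]
    bootstrap: dict[str, tuple[float, float]]
    permutation_p: dict[str, float]  # keyed "engineA|engineB"
    per_bin: dict[str, dict[str, float]]
    mean_sensitivity: dict[str, float]
    mean_ppv: dict[str, float]
    seed: int
    params_name: str
    params_checksum: str
    version: str = ""
    failures: list[str] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        obj = asdict(self)
        obj["bootstrap"] = {k: list(v) for k, v in self.bootstrap.items()}
        return obj

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_obj(), sort_keys=True, **kwargs)

    @classmethod
    def from_json_obj(cls, obj: dict) -> "BenchmarkReport":
        obj = dict(obj)
        obj["records"] = {
            k: [EvalRecord(**r) for r in v] for k, v in obj["records"].items()
        }
        obj["bootstrap"] = {k: tuple(v) for k, v in obj["bootstrap"].items()}
        return cls(**obj)


def read_manifest(path: str | Path) -> list[dict]:
    """Read a benchmark manifest: TSV with columns id, fasta, reference,
    format; paths are relative to the manifest's directory."""
    p = Path(path)
    base = p.parent
    rows = []
    lines = p.read_text().strip().splitlines()
    header = lines[0].split("\t")
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        row["fasta"] = str(base / row["fasta"])
        row["reference"] = str(base / row["reference"])
        rows.append(row)
    return rows


def run_benchmark(
    manifest: str | Path,
    engines: Sequence[str],
    params: EnergyParams,
    seed: int = 0,
    bootstrap_replicates: int = 10_000,
) -> BenchmarkReport:
    """Predict every manifest entry with every engine and compare.

    Unreadable entries are logged as failures and skipped; the run
    continues.  Fully reproducible under a fixed seed.
    """
    from . import __version__

    registry = _engine_registry()
    for name in engines:
        if name not in registry:
            raise ValueError(f"unknown engine {name!r}; choose from {ENGINE_NAMES}")
    rows = read_manifest(manifest)
    records: dict[str, list[EvalRecord]] = {name: [] for name in engines}
    failures: list[str] = []
    for row in rows:
        try:
            seq = read_fasta(Path(row["fasta"]).read_text())[0]
            ref = _READERS[row["format"]](Path(row["reference"]).read_text())
        except (OSError, KeyError, ValueError) as exc:
            failures.append(f"{row.get('id', '?')}: {exc}")
            continue
        for name in engines:
            try:
                pred = registry[name](seq, params)
            except ValueError as exc:
                failures.append(f"{row['id']}/{name}: {exc}")
                continue
            rec = accuracy(ref.structure, pred.structure, seq_id=row["id"])
            rec.energy = pred.energy
            records[name].append(rec)

    mean_f, cis, mean_s, mean_p = {}, {}, {}, {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(engines))
    for name, child in zip(engines, child_seeds):
        fs = [r.fmeasure for r in records[name]]
        if fs:
            mean_f[name] = float(np.mean(fs))
            cis[name] = bootstrap_ci(
                fs, replicates=bootstrap_replicates, seed=int(child)
            )
            mean_s[name] = float(np.mean([r.sensitivity for r in records[name]]))
            mean_p[name] = float(np.mean([r.ppv for r in records[name]]))
    pvals = {}
    perm_seed = int(ss.generate_state(len(engines) + 1)[-1])
    for a, b in itertools.combinations(engines, 2):
        fa = [r.fmeasure for r in records[a]]
        fb = [r.fmeasure for r in records[b]]
        if fa and fb:
            pvals[f"{a}|{b}"] = permutation_test(fa, fb, seed=perm_seed)
    per_bin = {name: bin_by_length(records[name]) for name in engines}
    return BenchmarkReport(
        engines=list(engines),
        records=records,
        mean_f=mean_f,
        bootstrap=cis,
        permutation_p=pvals,
        per_bin=per_bin,
        mean_sensitivity=mean_s,
        mean_ppv=mean_p,
        seed=seed,
        params_name=params.name,
        params_checksum=params.checksum(),
        version=__version__,
        failures=failures,
    )
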