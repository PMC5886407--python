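"""Accuracy metrics, bootstrap CIs, permutation tests, benchmark runner."""

import itertools
import json
import math

import numpy as np
import pytest

from knotfold.evaluate import (
    BenchmarkReport,
    accuracy,
    bin_by_length,
    bootstrap_ci,
    permutation_test,
    read_manifest,
    run_benchmark,
)
from knotfold.fixtures import FixtureSpec, default_benchmark_specs, make_manifest
from knotfold.structures import PairTable


def _pt(n, pairs):
    return PairTable.from_pairs(n, pairs)


class TestAccuracy:
    def test_perfect_prediction(self):
        ref = _pt(10, [(0, 9), (1, 8)])
        rec = accuracy(ref, _pt(10, [(0, 9), (1, 8)]))
        assert (rec.sensitivity, rec.ppv, rec.fmeasure) == (1.0, 1.0, 1.0)

    def test_disjoint_prediction_scores_zero(self):
        rec = accuracy(_pt(10, [(0, 9)]), _pt(10, [(1, 8)]))
        assert rec.fmeasure == 0.0

    def test_worked_example_four_ref_five_pred_three_correct(self):
        ref = _pt(20, [(0, 19), (1, 18), (2, 17), (3, 16)])
        pred = _pt(20, [(0, 19), (1, 18), (2, 17), (5, 12), (6, 11)])
        rec = accuracy(ref, pred)
        assert rec.sensitivity == pytest.approx(0.75)
        assert rec.ppv == pytest.approx(0.60)
        assert rec.fmeasure == pytest.approx(2 * 0.75 * 0.60 / 1.35)
        assert rec.fmeasure == pytest.approx(0.6667, abs=1e-4)

    def test_zero_denominator_rules(self):
        # empty prediction: PPV denominator is 0 -> 0; empty reference:
        # sensitivity denominator is 0 -> 0
        rec = accuracy(_pt(10, [(0, 9)]), _pt(10, []))
        assert (rec.sensitivity, rec.ppv, rec.fmeasure) == (0.0, 0.0, 0.0)
        rec = accuracy(_pt(10, []), _pt(10, [(0, 9)]))
        assert (rec.sensitivity, rec.ppv, rec.fmeasure) == (0.0, 0.0, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(Exception, match="length"):
            accuracy(_pt(10, []), _pt(11, []))


class TestBootstrap:
    def test_constant_vector_collapses_to_point(self):
        assert bootstrap_ci([0.5] * 30, seed=1) == (0.5, 0.5)

    def test_interval_ordered_and_reproducible(self):
        vals = list(np.random.default_rng(0).normal(0.6, 0.1, size=40))
        lo, hi = bootstrap_ci(vals, seed=7, replicates=2000)
        assert lo <= hi
        assert (lo, hi) == bootstrap_ci(vals, seed=7, replicates=2000)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])

    def test_coverage_of_the_mean(self):
        """95% percentile intervals cover the true mean ~95% of the time."""
        rng = np.random.default_rng(2024)
        true_mean, covered, trials = 0.6, 0, 1500
        for t in range(trials):
            vals = rng.normal(true_mean, 0.1, size=50)
            lo, hi = bootstrap_ci(vals, replicates=2000, seed=t)
            covered += lo <= true_mean <= hi
        assert 0.93 <= covered / trials <= 0.97


class TestPermutation:
    def test_identical_samples_give_p_one(self):
        assert permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_enumeration_matches_hand_count(self):
        x, y = [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]
        # same multiset split 3+3: every relabeling has |difference of
        # means| >= 0, so the hand count over C(6,3)=20 splits is 20/20
        assert permutation_test(x, y) == 1.0
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = x + y
        obs = abs(np.mean(x) - np.mean(y))
        hits = sum(
            1
            for c in itertools.combinations(pooled, 3)
            if abs(np.mean(c) - (sum(pooled) - sum(c)) / 3) >= obs - 1e-12
        )
        assert permutation_test(x, y) == pytest.approx(hits / 20)
        assert permutation_test(x, y) == pytest.approx(2 / 20)

    def test_symmetry(self):
        x = [0.2, 0.5, 0.9, 0.4]
        y = [0.1, 0.6, 0.3]
        assert permutation_test(x, y) == permutation_test(y, x)

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(3)
        x = list(rng.normal(0.5, 0.1, size=6))
        y = list(rng.normal(0.6, 0.1, size=6))
        p_exact = permutation_test(x, y)  # C(12,6)=924 -> exact branch
        # force the Monte-Carlo branch by shrinking the exact limit
        import knotfold.evaluate as ev

        old = ev.EXACT_PERMUTATION_LIMIT
        ev.EXACT_PERMUTATION_LIMIT = 1
        try:
            p_mc = permutation_test(x, y, seed=11, n_resamples=4000)
        finally:
            ev.EXACT_PERMUTATION_LIMIT = old
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) < 4 * se + 1e-3

    def test_type_i_error_rate_at_five_percent(self):
        """Under the null (identical distributions) the test rejects at
        alpha=0.05 about 5% of the time."""
        rng = np.random.default_rng(404)
        trials, rejections = 1000, 0
        for _ in range(trials):
            x = rng.normal(0.5, 0.1, size=5)
            y = rng.normal(0.5, 0.1, size=5)
            rejections += permutation_test(list(x), list(y)) < 0.05
        assert 0.03 <= rejections / trials <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])


class TestBinning:
    def test_half_open_boundaries(self):
        from knotfold.evaluate import EvalRecord, length_bin

        assert length_bin(50) == "[50,100)"
        assert length_bin(10) == "[10,50)"
        assert length_bin(400) == "[150,400]"
        assert length_bin(401) is None

    def test_mean_within_bin(self):
        from knotfold.evaluate import EvalRecord

        recs = [
            EvalRecord("a", 30, 1, 1, 0.4, "[10,50)"),
            EvalRecord("b", 40, 1, 1, 0.6, "[10,50)"),
        ]
        assert bin_by_length(recs) == {"[10,50)": pytest.approx(0.5)}

    def test_out_of_range_record_warns_and_excluded(self):
        from knotfold.evaluate import EvalRecord

        recs = [EvalRecord("tiny", 6, 1, 1, 0.9, None)]
        with pytest.warns(UserWarning, match="outside"):
            assert bin_by_length(recs) == {}

    def test_empty_bins_absent_not_zero(self):
        from knotfold.evaluate import EvalRecord

        recs = [EvalRecord("a", 200, 1, 1, 0.7, "[150,400]")]
        assert bin_by_length(recs) == {"[150,400]": pytest.approx(0.7)}


@pytest.fixture(scope="module")
def manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("bench")
    return make_manifest(default_benchmark_specs(), out)


class TestBenchmark:

    def test_manifest_rows_parse_back(self, manifest):
        rows = read_manifest(manifest)
        assert len(rows) == 10
        assert all(set(r) >= {"id", "fasta", "reference", "format"} for r in rows)

    def test_all_records_present(self, manifest, dp09):
        report = run_benchmark(manifest, ["mfe"], dp09, seed=3, bootstrap_replicates=200)
        assert len(report.records["mfe"]) == 10
        assert report.failures == []

    def test_full_report_and_json_roundtrip(self, manifest, dp09):
        report = run_benchmark(
            manifest, ["mfe", "greedy"], dp09, seed=3, bootstrap_replicates=200
        )
        lo, hi = report.bootstrap["mfe"]
        assert lo <= report.mean_f["mfe"] <= hi
        assert 0 < report.permutation_p["mfe|greedy"] <= 1
        obj = json.loads(report.to_json())
        back = BenchmarkReport.from_json_obj(obj)
        assert back.to_json() == report.to_json()

    def test_reproducible_under_fixed_seed(self, manifest, dp09):
        r1 = run_benchmark(manifest, ["mfe", "greedy"], dp09, seed=9,
                           bootstrap_replicates=200)
        r2 = run_benchmark(manifest, ["mfe", "greedy"], dp09, seed=9,
                           bootstrap_replicates=200)
        assert r1.to_json() == r2.to_json()

    def test_greedy_recovers_pseudoknots_mfe_cannot(self, manifest, dp09):
        report = run_benchmark(
            manifest, ["mfe", "greedy"], dp09, seed=1, bootstrap_replicates=200
        )
        # the battery contains H-type fixtures whose crossing stem the
        # pk-free engine can never predict
        assert report.mean_f["greedy"] > report.mean_f["mfe"]

    def test_unknown_engine_rejected(self, manifest, dp09):
        with pytest.raises(ValueError, match="unknown engine"):
            run_benchmark(manifest, ["quantum"], dp09, seed=0)

    def test_unreadable_reference_logged_and_run_continues(self, tmp_path, dp09):
        manifest = make_manifest(
            [FixtureSpec("hairpin", seed=0, params={"stem_len": 4, "loop_len": 4})],
            tmp_path,
        )
        text = manifest.read_text().splitlines()
        text.append("ghost\tmissing.fasta\tmissing.ct\tCT")
        manifest.write_text("\n".join(text) + "\n")
        report = run_benchmark(manifest, ["mfe"], dp09, seed=0,
                               bootstrap_replicates=100)
        assert len(report.records["mfe"]) == 1
        assert any("ghost" in f for f in report.failures)
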