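import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopescore import (
    CASE_REPORT_COUNTS,
    NON_SURVIVOR_PROBABILITIES,
    ConfusionTable,
    classify,
    confusion,
    diagnostic_report,
    roc_auc,
    wilson_interval,
)
from hopescore.diagnostics import _round_half_away


def brute_force_auc(pos, neg):
    """Exhaustive pairwise concordance: (concordant + ties/2) / (n1*n0)."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def wilson_closed_form(k, n, z=1.959963984540054):
    """Textbook Wilson score interval, written out independently."""
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


class TestClassify:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0992, False), (0.10, True), (0.147, True), (0.099999, False)],
    )
    def test_inclusive_threshold_on_unrounded_values(self, p, expected):
        assert classify(p, 0.10) is expected

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.1)
        with pytest.raises(ValueError):
            classify(0.5, 0.0)


class TestConfusion:
    def test_published_non_survivors_split_three_eight(self):
        """The eight published non-survivor probabilities, thresholded at
        10%, give 3 true negatives and 5 futile-rewarming false positives."""
        table = confusion(NON_SURVIVOR_PROBABILITIES, ["died"] * 8, 0.10)
        assert (table.tn, table.fp, table.tp, table.fn) == (3, 5, 0, 0)

    def test_empty_input_gives_all_zero_table(self):
        table = confusion([], [], 0.10)
        assert table.total == 0

    def test_counts_match_per_element_loop(self, rng):
        probs = rng.random(50)
        outcomes = rng.random(50) < 0.6
        table = confusion(probs, outcomes, 0.3)
        tp = sum(1 for p, y in zip(probs, outcomes) if p >= 0.3 and y)
        fp = sum(1 for p, y in zip(probs, outcomes) if p >= 0.3 and not y)
        tn = sum(1 for p, y in zip(probs, outcomes) if p < 0.3 and not y)
        fn = sum(1 for p, y in zip(probs, outcomes) if p < 0.3 and y)
        assert (table.tp, table.fp, table.tn, table.fn) == (tp, fp, tn, fn)

    def test_missing_outcomes_excluded_and_tallied(self):
        table = confusion([0.2, 0.05, 0.8], ["survived", None, float("nan")], 0.1)
        assert table.total == 1 and table.n_missing_outcome == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0.5], ["survived", "died"], 0.1)

    def test_threshold_sweep_monotonicity(self, rng):
        """Raising the threshold never increases sensitivity nor decreases
        specificity."""
        probs = rng.random(200)
        outcomes = rng.random(200) < probs
        prev_sens, prev_spec = 1.1, -0.1
        for thr in np.linspace(0.05, 0.95, 19):
            t = confusion(probs, outcomes, thr)
            sens = t.tp / (t.tp + t.fn)
            spec = t.tn / (t.tn + t.fp)
            assert sens <= prev_sens + 1e-12
            assert spec >= prev_spec - 1e-12
            prev_sens, prev_spec = sens, spec


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,low_pct,high_pct",
        [(3, 8, 14, 69), (3, 4, 30, 95), (61, 62, 91, 100), (61, 66, 83, 97),
         (5, 70, 3, 16), (1, 70, 0, 8)],
    )
    def test_published_intervals_at_integer_percent(self, k, n, low_pct, high_pct):
        low, high = wilson_interval(k, n, 0.95)
        assert _round_half_away(low * 100) == low_pct
        assert _round_half_away(high * 100) == high_pct

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(1, 200), data=st.data())
    def test_matches_textbook_closed_form(self, n, data):
        k = data.draw(st.integers(0, n))
        low, high = wilson_interval(k, n, 0.95)
        exp_low, exp_high = wilson_closed_form(k, n)
        assert low == pytest.approx(exp_low, abs=1e-9)
        assert high == pytest.approx(exp_high, abs=1e-9)
        assert 0.0 <= low <= k / n <= high <= 1.0

    def test_boundary_counts(self):
        assert wilson_interval(0, 10)[0] == 0.0
        assert wilson_interval(10, 10)[1] == 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    def test_coverage_matches_analytic_wilson_coverage(self, rng):
        """Empirical coverage over 10,000 binomial draws at p=0.3, n=20
        agrees with the exact coverage of the Wilson interval (obtained by
        summing the binomial pmf over covered counts) within Monte-Carlo
        error."""
        from scipy.stats import binom

        p_true, n = 0.3, 20
        covered_counts = [
            k for k in range(n + 1)
            if wilson_interval(k, n)[0] <= p_true <= wilson_interval(k, n)[1]
        ]
        exact_coverage = binom.pmf(covered_counts, n, p_true).sum()
        draws = rng.binomial(n, p_true, size=10_000)
        empirical = np.isin(draws, covered_counts).mean()
        mc_se = math.sqrt(exact_coverage * (1 - exact_coverage) / 10_000)
        assert abs(empirical - exact_coverage) < 4 * mc_se


class TestDiagnosticReport:
    def test_published_cohort_metrics(self):
        report = diagnostic_report(CASE_REPORT_COUNTS)
        assert report.sensitivity.value == pytest.approx(61 / 62)
        assert report.specificity.value == pytest.approx(3 / 8)
        assert report.ppv.value == pytest.approx(61 / 66)
        assert report.npv.value == pytest.approx(3 / 4)
        assert report.fp_fraction.value == pytest.approx(5 / 70)
        assert report.fn_fraction.value == pytest.approx(1 / 70)
        assert report.specificity.display() == "3/8 = 38% (14-69%)"
        assert report.sensitivity.display() == "61/62 = 98% (91-100%)"
        assert report.correct_decision_fraction().value == pytest.approx(64 / 70)

    def test_undefined_metrics_surfaced_not_zeroed(self):
        report = diagnostic_report(ConfusionTable(tp=10, fp=0, tn=0, fn=0))
        assert report.sensitivity.value == 1.0
        assert not report.specificity.defined
        assert "undefined" in report.specificity.display()
        assert not report.npv.defined

    def test_random_tables_match_hand_ratios(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            r = diagnostic_report(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn))
            assert r.sensitivity.value == pytest.approx(tp / (tp + fn))
            assert r.specificity.value == pytest.approx(tn / (tn + fp))
            assert r.ppv.value == pytest.approx(tp / (tp + fp))
            assert r.npv.value == pytest.approx(tn / (tn + fn))
            for m in r.metrics():
                assert m.ci_low <= m.value <= m.ci_high


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_tied_probabilities(self):
        r = roc_auc([0.5] * 10, [1, 0] * 5)
        assert r.auc == 0.5

    def test_matches_brute_force_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 31))
            probs = np.round(rng.random(n), 2)  # rounding forces some ties
            outcomes = rng.random(n) < 0.5
            if outcomes.all() or not outcomes.any():
                continue
            r = roc_auc(probs, outcomes)
            expected = brute_force_auc(probs[outcomes], probs[~outcomes])
            assert r.auc == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        probs = rng.random(100)
        outcomes = rng.random(100) < probs
        r = roc_auc(probs, outcomes)
        assert r.auc == pytest.approx(roc_auc_score(outcomes, probs), abs=1e-12)

    def test_curve_shape_and_trapezoid_identity(self, rng):
        probs = np.round(rng.random(60), 1)
        outcomes = rng.random(60) < probs
        r = roc_auc(probs, outcomes)
        fpr = np.array([p[0] for p in r.curve])
        tpr = np.array([p[1] for p in r.curve])
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert abs(np.trapezoid(tpr, fpr) - r.auc) < 1e-10

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 0.99), min_size=6, max_size=40))
    def test_invariant_under_strictly_increasing_transform(self, probs):
        outcomes = [i % 2 for i in range(len(probs))]
        base = roc_auc(probs, outcomes).auc
        squashed = roc_auc([p**3 / (p**3 + (1 - p) ** 3) for p in probs], outcomes).auc
        assert squashed == pytest.approx(base, abs=1e-12)

    def test_delong_interval_contains_point_estimate(self, rng):
        probs = rng.random(80)
        outcomes = rng.random(80) < probs
        r = roc_auc(probs, outcomes)
        assert r.ci_low <= r.auc <= r.ci_high
        assert r.ci_method == "delong"

    def test_single_member_class_degrades_to_bootstrap(self, rng):
        probs = [0.9, 0.4, 0.3, 0.2, 0.6]
        outcomes = [1, 0, 0, 0, 0]
        r = roc_auc(probs, outcomes)
        assert "bootstrap" in r.ci_method and "degenerate" in r.ci_method
        assert 0.0 <= r.ci_low <= r.ci_high <= 1.0

    def test_single_class_rejected_naming_missing_class(self):
        with pytest.raises(ValueError, match="non-survivors"):
            roc_auc([0.2, 0.4], [1, 1])
        with pytest.raises(ValueError, match="survivors"):
            roc_auc([0.2, 0.4], [0, 0])

    def test_agrees_with_r_proc_delong(self, tmp_path):
        """Cross-check AUC and DeLong CI against the pROC reference
        implementation on a fixed small cohort."""
        import json
        import subprocess

        rng = np.random.default_rng(7)
        probs = np.round(rng.random(40), 3)
        outcomes = (rng.random(40) < probs).astype(int)
        if outcomes.all() or not outcomes.any():  # pragma: no cover
            pytest.fail("degenerate fixture")
        script = tmp_path / "proc.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"p <- c({', '.join(map(str, probs.tolist()))})\n"
            f"y <- c({', '.join(map(str, outcomes.tolist()))})\n"
            "r <- roc(y, p, levels = c(0, 1), direction = '<', quiet = TRUE)\n"
            "ci <- ci.auc(r, method = 'delong')\n"
            "cat(sprintf('{\"auc\": %.12f, \"lo\": %.12f, \"hi\": %.12f}',\n"
            "    as.numeric(auc(r)), ci[1], ci[3]))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        r = roc_auc(probs, outcomes)
        assert r.auc == pytest.approx(ref["auc"], abs=1e-10)
        assert r.ci_low == pytest.approx(ref["lo"], abs=1e-9)
        assert r.ci_high == pytest.approx(ref["hi"], abs=1e-9)
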