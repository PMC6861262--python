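import numpy as np
import pytest

import swarmdx as sx
from swarmdx import CaseSet, ConfusionMatrix, DiagnosisSet, ValidationError

from conftest import make_diag


class TestConfusionMatrixMetrics:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(tp=18, fp=7, tn=23, fn=2), 82.0),
            (ConfusionMatrix(tp=35, fp=4, tn=56, fn=5), 91.0),
            (ConfusionMatrix(tp=20, fp=0, tn=30, fn=0), 100.0),
        ],
    )
    def test_percent_correct(self, cm, expected):
        assert sx.percent_correct(cm) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cm,expected,tol",
        [
            (ConfusionMatrix(tp=18, fp=7, tn=23, fn=2), 0.800, 5e-4),
            (ConfusionMatrix(tp=28, fp=4, tn=56, fn=12), 0.778, 5e-4),
            (ConfusionMatrix(tp=9, fp=0, tn=5, fn=0), 1.0, 0),
        ],
    )
    def test_f1(self, cm, expected, tol):
        assert sx.f1(cm) == pytest.approx(expected, abs=tol + 1e-12)

    def test_f1_zero_tp_warns(self):
        with pytest.warns(UserWarning):
            assert sx.f1(ConfusionMatrix(tp=0, fp=3, tn=5, fn=2)) == 0.0

    def test_sensitivity_specificity(self):
        cm = ConfusionMatrix(tp=14, fn=6, tn=28, fp=2)
        assert sx.sensitivity(cm) == pytest.approx(0.700)
        assert sx.specificity(cm) == pytest.approx(28 / 30)

    def test_degenerate_errors(self):
        with pytest.raises(ValidationError):
            sx.percent_correct(ConfusionMatrix(0, 0, 0, 0))
        with pytest.raises(ValidationError):
            sx.sensitivity(ConfusionMatrix(tp=0, fp=3, tn=5, fn=0))

    def test_recomposition_from_class_rates(self):
        # percent correct is the prevalence-weighted mix of sens and spec
        cm = ConfusionMatrix(tp=18, fp=7, tn=23, fn=2)
        mix = (sx.sensitivity(cm) * cm.n_pos + sx.specificity(cm) * cm.n_neg) / cm.total
        assert sx.percent_correct(cm) == pytest.approx(100 * mix)


class TestProbabilisticMetrics:
    def test_mae_brier_simple(self):
        cases = CaseSet(("a",), (0,))
        d = make_diag([0.1], ("a",))
        assert sx.mae(d, cases) == pytest.approx(0.1)
        assert sx.brier(d, cases) == pytest.approx(0.01)

    def test_perfect_probabilities(self, small_cases):
        d = make_diag([0.0, 0.0, 1.0, 1.0])
        assert sx.mae(d, small_cases) == 0.0
        assert sx.brier(d, small_cases) == 0.0

    def test_uninformative_brier(self, small_cases):
        d = make_diag([0.5] * 4)
        assert sx.brier(d, small_cases) == pytest.approx(0.25)

    def test_matches_loop_oracle_and_brier_le_mae(self, random_study):
        cases, diag = random_study
        mae_loop = np.mean(
            [abs(diag.probabilities[c] - l) for c, l in zip(cases.case_ids, cases.labels)]
        )
        brier_loop = np.mean(
            [(diag.probabilities[c] - l) ** 2 for c, l in zip(cases.case_ids, cases.labels)]
        )
        assert sx.mae(diag, cases) == pytest.approx(mae_loop, abs=1e-12)
        assert sx.brier(diag, cases) == pytest.approx(brier_loop, abs=1e-12)
        assert sx.brier(diag, cases) <= sx.mae(diag, cases)

    def test_binary_probs_collapse_to_error_rate(self, small_cases):
        d = make_diag([0.0, 1.0, 1.0, 0.0])  # one FP, one FN
        err = 0.5
        assert sx.mae(d, small_cases) == pytest.approx(err)
        assert sx.brier(d, small_cases) == pytest.approx(err)


def _auc_brute(probs, labels):
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_pair_counting_example(self, small_cases):
        d = make_diag([0.3, 0.5, 0.9, 0.4])
        assert sx.auc(d, small_cases) == pytest.approx(0.75)

    def test_perfect_separation(self, small_cases):
        assert sx.auc(make_diag([0.1, 0.2, 0.8, 0.9]), small_cases) == 1.0

    def test_all_ties(self, small_cases):
        assert sx.auc(make_diag([0.4] * 4), small_cases) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self, random_study, rng):
        cases, diag = random_study
        probs = diag.aligned(cases)
        assert sx.auc(diag, cases) == pytest.approx(
            _auc_brute(probs, cases.labels), abs=1e-12
        )

    def test_refuses_mixed_scale_augmented(self, small_cases):
        d = DiagnosisSet(
            "aug", "augmented", {"a": 0.01, "b": 0.02, "c": 0.6, "d": 0.7},
            provenance={"a": "ml", "b": "ml", "c": "sw", "d": "sw"},
        )
        with pytest.raises(ValidationError, match="mixed-scale"):
            sx.auc(d, small_cases)

    def test_single_class_error(self):
        cases = CaseSet(("a", "b"), (1, 1))
        with pytest.raises(ValidationError):
            sx.auc(make_diag([0.2, 0.8], ("a", "b")), cases)


class TestBootstrapCI:
    def test_degenerate_ci_on_constant_correct(self, small_cases):
        d = make_diag([0.0, 0.0, 1.0, 1.0])
        rep = sx.bootstrap_ci("percent_correct", d, small_cases, n_boot=200, seed=1)
        assert rep.ci_lower == rep.value == rep.ci_upper == 100.0

    def test_fixed_seed_reproducible(self, random_study):
        cases, diag = random_study
        a = sx.bootstrap_ci("brier", diag, cases, n_boot=300, seed=42)
        b = sx.bootstrap_ci("brier", diag, cases, n_boot=300, seed=42)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_ci_brackets_point(self, random_study):
        cases, diag = random_study
        rep = sx.bootstrap_ci("mae", diag, cases, n_boot=500, seed=7)
        assert rep.ci_lower - 1e-9 <= rep.value <= rep.ci_upper + 1e-9

    def test_width_shrinks_with_case_count(self):
        op = sx.OperatingPoint(0.9, 0.767, 0.04008, sigma=0.8)
        widths = {}
        for n in (50, 500):
            cases = sx.gen_cases(n, 0.4, seed=5)
            d = sx.gen_probs(cases, op, seed=6, source_id="ml", kind="ml")
            rep = sx.bootstrap_ci(
                "percent_correct", d, cases, n_boot=400, seed=8, threshold=0.04008
            )
            widths[n] = rep.ci_upper - rep.ci_lower
        assert widths[500] < widths[50]

    def test_stratified_preserves_class_balance(self, random_study):
        cases, diag = random_study
        rep = sx.bootstrap_ci("sensitivity", diag, cases, n_boot=200, seed=3,
                              stratified=True)
        assert rep.n_redraws == 0


class TestIndividualAverage:
    def test_pooled_vs_group_mean_agree_for_identical_readers(self, random_study):
        cases, diag = random_study
        panel = [diag, DiagnosisSet("copy", "reader", dict(diag.probabilities))]
        for variant in ("pooled", "group_mean"):
            assert sx.individual_average(
                panel, cases, "percent_correct", variant=variant
            ) == pytest.approx(sx.evaluate("percent_correct", diag, cases))

    def test_group_mean_is_unweighted_mean(self, random_study):
        cases, diag = random_study
        flipped = DiagnosisSet("f", "reader",
                               {c: 1.0 - p for c, p in diag.probabilities.items()})
        gm = sx.individual_average([diag, flipped], cases, "mae", variant="group_mean")
        expected = 0.5 * (sx.mae(diag, cases) + sx.mae(flipped, cases))
        assert gm == pytest.approx(expected, abs=1e-12)

    def test_pooled_weights_by_diagnosis_count(self, random_study):
        cases, diag = random_study
        clones = [DiagnosisSet(f"r{i}", "reader", dict(diag.probabilities))
                  for i in range(3)]
        pooled = sx.individual_average(clones, cases, "brier")
        assert pooled == pytest.approx(sx.brier(diag, cases), abs=1e-12)


class TestPairedBootstrap:
    def test_identical_sets_p_one(self, random_study):
        cases, diag = random_study
        assert sx.paired_bootstrap_pvalue(diag, diag, "brier", cases, n_boot=100, seed=0) == 1.0

    def test_detects_large_accuracy_gap(self):
        cases = sx.gen_cases(200, 0.5, seed=1)
        good = sx.gen_probs(cases, sx.OperatingPoint(0.95, 0.95, 0.5), seed=2, source_id="g")
        bad = sx.gen_probs(cases, sx.OperatingPoint(0.6, 0.6, 0.5), seed=3, source_id="b")
        p = sx.paired_bootstrap_pvalue(good, bad, "percent_correct", cases,
                                       n_boot=500, seed=4)
        assert p < 0.05

    def test_seed_reproducible(self, random_study):
        cases, diag = random_study
        other = DiagnosisSet("o", "reader",
                             {c: 1.0 - p for c, p in diag.probabilities.items()})
        p1 = sx.paired_bootstrap_pvalue(diag, other, "mae", cases, n_boot=300, seed=9)
        p2 = sx.paired_bootstrap_pvalue(diag, other, "mae", cases, n_boot=300, seed=9)
        assert p1 == p2
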