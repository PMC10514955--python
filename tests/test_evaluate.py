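"""Evaluation statistics: confusion-matrix metrics, G-mean, coverage
violation over evaluation units, and rejection profiles."""

import math

import numpy as np
import pytest

from selanet import (ConfusionCounts, classification_metrics,
                     coverage_violation, gmean, rejection_profile)
from selanet.selective import Decision


class TestClassificationMetrics:
    def test_hand_computed_example(self):
        m = classification_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["fnr"] == pytest.approx(0.4)
        assert m["fpr"] == pytest.approx(0.2)
        assert m["f1"] == pytest.approx(6 / 9)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity",
                                         "specificity", "f1"))
        assert m["fnr"] == 0.0 and m["fpr"] == 0.0

    def test_all_positives_missed(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=4))
        assert m["sensitivity"] == 0.0 and m["f1"] == 0.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["fnr"])

    def test_complement_identities_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 100, size=4)
            m = classification_metrics(ConfusionCounts(int(tp), int(tn),
                                                       int(fp), int(fn)))
            assert m["fnr"] == pytest.approx(1 - m["sensitivity"], abs=1e-12)
            assert m["fpr"] == pytest.approx(1 - m["specificity"], abs=1e-12)

    def test_from_labels(self):
        y = np.array(["apnea", "apnea", "normal", "normal", "apnea"])
        p = np.array(["apnea", "normal", "normal", "apnea", "apnea"])
        c = ConfusionCounts.from_labels(y, p)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


class TestGmean:
    @pytest.mark.parametrize("s,p,expected", [
        (0.6, 0.8, math.sqrt(0.48)), (1.0, 1.0, 1.0), (0.0, 0.7, 0.0)])
    def test_values(self, s, p, expected):
        assert gmean(s, p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            gmean(1.2, 0.5)


class TestCoverageViolation:
    def test_two_unit_example(self):
        g = np.concatenate([np.full(64, 0.8), np.full(64, 1.0)])
        assert coverage_violation(g, c=0.9) == pytest.approx(0.1)

    def test_exact_coverage_gives_zero(self):
        g = np.full(128, 0.95)
        assert coverage_violation(g, c=0.95) == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_uses_plain_difference(self):
        g = np.full(50, 0.897)
        assert coverage_violation(g, c=0.90) == pytest.approx(0.003)

    def test_grouped_units(self):
        g = np.array([0.8, 0.8, 1.0, 1.0])
        groups = np.array(["s1", "s1", "s2", "s2"])
        assert coverage_violation(g, c=0.9, groups=groups) == pytest.approx(0.1)

    def test_dispersion_bound(self):
        # violation over units >= |c - overall mean| (triangle inequality)
        rng = np.random.default_rng(3)
        g = rng.uniform(0, 1, size=500)
        c = 0.9
        assert coverage_violation(g, c) >= abs(c - g.mean()) - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coverage_violation([], 0.9)


class TestRejectionProfile:
    def _dec(self, cls, g=0.5):
        return Decision(selected=cls != "reject", predicted_class=cls, g_score=g)

    def test_all_rejected(self):
        decisions = [self._dec("reject")] * 4
        prof = rejection_profile(decisions, ["apnea", "apnea", "normal", "ambiguous"])
        for stream in prof.values():
            assert stream["rejected_pct"] == 100.0
            assert stream["predicted_apnea_pct"] == 0.0

    def test_none_rejected_at_tau_zero(self):
        decisions = [self._dec("apnea"), self._dec("normal")]
        prof = rejection_profile(decisions, ["apnea", "normal"])
        assert all(s["rejected_pct"] == 0.0 for s in prof.values())

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        classes = ["apnea", "normal", "reject"]
        decisions = [self._dec(classes[i]) for i in rng.integers(0, 3, 200)]
        streams = rng.choice(["apnea", "normal", "ambiguous"], 200)
        prof = rejection_profile(decisions, streams)
        for stream in prof.values():
            total = sum(stream.values())
            assert total == pytest.approx(100.0, abs=0.01)

    def test_empty_stream_warns_and_is_omitted(self):
        decisions = [self._dec("apnea")]
        with pytest.warns(UserWarning, match="ambiguous"):
            prof = rejection_profile(decisions, ["apnea"],
                                     expected=("apnea", "ambiguous"))
        assert "ambiguous" not in prof and "apnea" in prof


def test_summarize_reports_mean_sd():
    from selanet.evaluate import EvalReport, summarize_reports
    base = dict(target_coverage=0.9, tau=0.9, n_test=10,
                selected={"accuracy": 0.9}, no_selection={"accuracy": 0.8},
                gmean_selected=0.85, selective_risk=0.1, selected_fraction=0.9)
    r1 = EvalReport(mean_empirical_coverage=0.88, coverage_violation=0.02, **base)
    r2 = EvalReport(mean_empirical_coverage=0.92, coverage_violation=0.04, **base)
    summary = summarize_reports([r1, r2])
    assert summary.loc["mean_empirical_coverage", "mean"] == pytest.approx(0.90)
    assert summary.loc["coverage_violation", "sd"] == pytest.approx(
        np.std([0.02, 0.04], ddof=1))


def test_metrics_recomputable_from_counts_to_high_precision():
    rng = np.random.default_rng(11)
    counts = ConfusionCounts(*map(int, rng.integers(1, 500, 4)))
    m = classification_metrics(counts)
    # recompute from the emitted counts; must agree to 1e-12
    assert m["accuracy"] == pytest.approx(
        (counts.tp + counts.tn) / counts.total, abs=1e-12)
    assert m["f1"] == pytest.approx(
        2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn), abs=1e-12)
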