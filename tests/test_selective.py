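"""Selective-prediction arithmetic (coverage, risk, penalty, convex
combination) against brute-force recomputation, plus the decision rule."""

import numpy as np
import pytest

from selanet import (LossBreakdown, SelectiveClassifier, TrainConfig,
                     build_selective_model, combined_loss, empirical_coverage,
                     predict_with_rejection, psi, selective_loss,
                     selective_risk)


# ---------------------------------------------------------------------------
# brute-force oracle: literal loops over the defining sums
# ---------------------------------------------------------------------------

def brute_force_losses(p_f, g, y, c, lam, p_h=None, alpha=None):
    m = len(g)
    phi = sum(g) / m
    ell = [-np.log(p_f[i][y[i]]) for i in range(m)]
    risk = 0.0 if phi == 0 else (sum(ell[i] * g[i] for i in range(m)) / m) / phi
    pen = lam * max(0.0, c - phi) ** 2
    l_fg = risk + pen
    out = {"phi": phi, "risk": risk, "penalty": pen, "l_fg": l_fg}
    if p_h is not None:
        l_h = sum(-np.log(p_h[i][y[i]]) for i in range(m)) / m
        out["l_h"] = l_h
        out["total"] = alpha * l_fg + (1 - alpha) * l_h
    return out


class TestPsi:
    @pytest.mark.parametrize("a,expected", [(0.5, 0.25), (-1.0, 0.0), (0.0, 0.0)])
    def test_values(self, a, expected):
        assert psi(a) == expected

    def test_vectorised(self):
        assert np.allclose(psi(np.array([-2.0, 0.3])), [0.0, 0.09])


class TestCoverageAndRisk:
    def test_coverage_examples(self):
        assert empirical_coverage([1, 1, 0, 0]) == 0.5
        assert empirical_coverage([1.0] * 7) == 1.0
        assert empirical_coverage([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            empirical_coverage([])

    def test_risk_examples(self):
        assert selective_risk([1, 0, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.5)
        assert selective_risk([0, 0, 0], [0.3, 0.9, 0.5]) == 0.0
        # uniform confidence cancels: risk equals the plain mean loss
        losses = [0.2, 0.7, 0.1]
        assert selective_risk(losses, [0.6] * 3) == pytest.approx(np.mean(losses))
        with pytest.raises(ValueError):
            selective_risk([1.0], [0.0])


class TestSelectiveLoss:
    def test_perfect_prediction_full_confidence_is_zero(self):
        p_f = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        out = selective_loss(np.clip(p_f, 1e-300, 1), [1.0, 1.0], y, c=0.9, lam=200)
        assert out.selective_loss == pytest.approx(0.0, abs=1e-12)

    def test_penalty_arithmetic(self):
        # all g = 0.5 at c = 0.98: penalty 200 * 0.48^2 = 46.08 on top of risk
        p_f = np.array([[0.6, 0.4], [0.3, 0.7]])
        y = np.array([0, 1])
        out = selective_loss(p_f, [0.5, 0.5], y, c=0.98, lam=200)
        assert out.coverage_penalty == pytest.approx(200 * 0.48**2)
        assert out.selective_loss == pytest.approx(
            out.selective_risk_term + 46.08)

    def test_risk_with_mixed_confidence(self):
        # losses [0, 1] with g [1, 0.5]: phi 0.75 >= c, risk (0+0.5)/2/0.75
        p_f = np.array([[1.0, 0.0], [1 - 1 / np.e, 1 / np.e]])
        y = np.array([0, 1])
        out = selective_loss(p_f, [1.0, 0.5], y, c=0.5, lam=200)
        assert out.coverage_penalty == 0.0
        assert out.selective_risk_term == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_coverage_batch_keeps_full_penalty(self):
        p_f = np.array([[0.7, 0.3]])
        out = selective_loss(p_f, [0.0], np.array([0]), c=0.9, lam=100)
        assert out.selective_risk_term == 0.0
        assert out.coverage_penalty == pytest.approx(100 * 0.81)


class TestCombinedLoss:
    def test_convex_combination_example(self):
        sel = LossBreakdown(coverage=0.9, selective_risk_term=0.0,
                            coverage_penalty=32.5, selective_loss=32.5)
        p_h = np.array([[np.exp(-0.7), 1 - np.exp(-0.7)]])
        out = combined_loss(sel, p_h, np.array([0]), alpha=0.3)
        assert out.total == pytest.approx(0.3 * 32.5 + 0.7 * 0.7)
        assert out.total == pytest.approx(10.24, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_boundary_alphas(self, alpha):
        sel = LossBreakdown(coverage=1, selective_risk_term=0.5,
                            coverage_penalty=0.0, selective_loss=0.5)
        p_h = np.array([[0.8, 0.2], [0.6, 0.4]])
        y = np.array([0, 0])
        out = combined_loss(sel, p_h, y, alpha=alpha)
        if alpha == 1.0:
            assert out.total == pytest.approx(out.selective_loss)
        else:
            assert out.total == pytest.approx(out.auxiliary_loss)


def test_loss_oracle_on_many_random_batches():
    # the formulas must agree with literal brute-force sums to 1e-10
    rng = np.random.default_rng(99)
    for _ in range(1000):
        m = int(rng.integers(1, 65))
        logits = rng.normal(size=(m, 2))
        p_f = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        p_h = rng.dirichlet([1, 1], size=m)
        g = rng.uniform(0, 1, size=m)
        y = rng.integers(0, 2, size=m)
        c = float(rng.uniform(0.5, 1.0))
        lam = float(rng.uniform(0, 300))
        alpha = float(rng.uniform(0, 1))
        sel = selective_loss(p_f, g, y, c, lam)
        full = combined_loss(sel, p_h, y, alpha)
        bf = brute_force_losses(p_f, g, y, c, lam, p_h, alpha)
        assert abs(sel.coverage - bf["phi"]) < 1e-10
        assert abs(sel.selective_risk_term - bf["risk"]) < 1e-10
        assert abs(sel.selective_loss - bf["l_fg"]) < 1e-10
        assert abs(full.auxiliary_loss - bf["l_h"]) < 1e-10
        assert abs(full.total - bf["total"]) < 1e-10


class TestModelSurface:
    @pytest.fixture(scope="class")
    def toy_fit(self):
        # linearly separable toy latents: class decided by channel mean
        rng = np.random.default_rng(5)
        n = 256
        Z = rng.normal(0, 0.3, size=(n, 150, 8)).astype(np.float32)
        y = np.where(rng.uniform(size=n) < 0.5, "apnea", "normal")
        Z[y == "apnea", :, 0] += 1.0
        clf = SelectiveClassifier(target_coverage=0.9, epochs=8,
                                  random_state=0)
        clf.fit(Z, y)
        return clf, Z, y

    def test_forward_contracts(self, toy_fit):
        clf, Z, _ = toy_fit
        p = clf.predict_proba(Z[:10])
        g = clf.confidence_scores(Z[:10])
        assert p.shape == (10, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((g >= 0) & (g <= 1))

    def test_decision_rule_thresholds(self, toy_fit):
        clf, Z, _ = toy_fit
        g = clf.confidence_scores(Z)
        decisions = predict_with_rejection(clf, Z, tau=float(np.median(g)))
        for d, gi in zip(decisions, g):
            assert d.selected == (gi >= np.median(g))
            assert (d.predicted_class == "reject") == (not d.selected)
        # tau = 0 selects everything
        assert all(d.selected for d in clf.decide(Z, tau=0.0))

    def test_selected_fraction_monotone_in_tau(self, toy_fit):
        clf, Z, _ = toy_fit
        fracs = [np.mean([d.selected for d in clf.decide(Z, tau=t)])
                 for t in np.linspace(0, 1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_history_logs_epoch_records(self, toy_fit):
        clf, _, _ = toy_fit
        assert len(clf.history_) == 8
        for col in ("total", "l_fg", "l_h", "coverage", "risk", "penalty"):
            assert col in clf.history_.columns

    def test_embeddings_shape(self, toy_fit):
        clf, Z, _ = toy_fit
        E = clf.embeddings(Z[:12])
        assert E.shape == (12, clf.lstm_units)
        assert np.isfinite(E).all()

    def test_save_load_roundtrip(self, toy_fit, tmp_path):
        clf, Z, _ = toy_fit
        clf.save(tmp_path / "m.npz")
        clone = SelectiveClassifier.load(tmp_path / "m.npz")
        assert np.allclose(clone.confidence_scores(Z[:16]),
                           clf.confidence_scores(Z[:16]), atol=1e-6)
        assert list(clone.classes_) == list(clf.classes_)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(target_coverage=0.0)
    with pytest.raises(ValueError):
        TrainConfig(alpha=1.5)
    cfg = TrainConfig()
    assert cfg.lam == 200.0 and cfg.alpha == 0.3 and cfg.batch_size == 64
    model = build_selective_model(config=cfg)
    assert model.target_coverage == 0.98
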