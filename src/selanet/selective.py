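"""Coverage-constrained selective classification with a reject option.

A shared 1-D CNN-LSTM body over the (150, 8) latent feeds three heads:

* prediction head ``f`` — two-class softmax (apnea vs normal);
* selection head ``g`` — fully-connected layer, batch normalisation and a
  sigmoid, emitting a confidence score in [0, 1];
* auxiliary head ``h`` — two-class softmax trained with plain cross-entropy
  to keep the shared body discriminative while ``g`` learns to select.

Prediction accepts a sample when ``g(x) >= tau`` and answers "don't know"
otherwise.  Training minimises a convex combination

    L = alpha * [ r_hat(f, g) + lambda * psi(c - phi_hat(g)) ] + (1 - alpha) * L_h

where ``phi_hat`` is the empirical coverage (mean confidence of the
minibatch), ``r_hat`` the confidence-weighted selective risk, ``psi(a) =
max(0, a)^2`` an interior-point penalty pulling empirical coverage up to the
target coverage ``c``, and ``L_h`` the auxiliary cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import autodiff as ad
from .nn.layers import BatchNorm1d, Conv1d, Dense, LSTM, Module
from .nn.optim import Adam

CLASSES = ("apnea", "normal")
REJECT = "reject"


# ---------------------------------------------------------------------------
# loss arithmetic (float64; the exact empirical formulas)
# ---------------------------------------------------------------------------

def psi(a):
    """Interior-point coverage penalty kernel: max(0, a)^2."""
    return np.maximum(0.0, np.asarray(a, dtype=np.float64)) ** 2 if np.ndim(a) \
        else float(max(0.0, float(a)) ** 2)


def empirical_coverage(g_scores) -> float:
    """Mean confidence score over the sample set."""
    g = np.asarray(g_scores, dtype=np.float64)
    if g.size == 0:
        raise ValueError("empirical coverage of an empty sample set")
    return float(g.mean())


def selective_risk(per_sample_losses, g_scores) -> float:
    """Confidence-weighted mean loss normalised by empirical coverage."""
    losses = np.asarray(per_sample_losses, dtype=np.float64)
    g = np.asarray(g_scores, dtype=np.float64)
    if losses.shape != g.shape:
        raise ValueError("losses and confidence scores must align")
    phi = empirical_coverage(g)
    if phi == 0:
        raise ValueError("selective risk undefined at zero coverage")
    return float((losses * g).mean() / phi)


@dataclass
class LossBreakdown:
    """All terms of the training objective, exposed for logging and tests."""

    coverage: float                    # phi_hat, mean g over the batch
    selective_risk_term: float         # r_hat
    coverage_penalty: float            # lambda * psi(c - phi_hat)
    selective_loss: float              # L_(f,g) = r_hat + penalty
    auxiliary_loss: float | None = None
    total: float | None = None


def _cross_entropy_from_proba(p: np.ndarray, labels: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    return -np.log(p[np.arange(len(labels)), labels])


def selective_loss(p_f, g_scores, labels, c: float, lam: float) -> LossBreakdown:
    """Selective objective on one batch: r_hat + lambda * psi(c - phi_hat).

    ``p_f`` are prediction-head class probabilities, ``labels`` integer class
    indices; the per-sample loss inside the risk is cross-entropy.  A batch
    with phi_hat = 0 gets risk term 0 and the full coverage penalty (the
    penalty gradient is what pushes g back up).
    """
    g = np.asarray(g_scores, dtype=np.float64)
    if g.size == 0:
        raise ValueError("empty batch")
    losses = _cross_entropy_from_proba(p_f, labels)
    phi = empirical_coverage(g)
    risk = 0.0 if phi == 0 else float((losses * g).mean() / phi)
    penalty = lam * psi(c - phi)
    return LossBreakdown(coverage=phi, selective_risk_term=risk,
                         coverage_penalty=float(penalty),
                         selective_loss=float(risk + penalty))


def combined_loss(selective: LossBreakdown, p_h, labels, alpha: float) -> LossBreakdown:
    """Convex combination of selective and auxiliary (cross-entropy) losses."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    l_h = float(_cross_entropy_from_proba(p_h, labels).mean())
    total = alpha * selective.selective_loss + (1 - alpha) * l_h
    return LossBreakdown(coverage=selective.coverage,
                         selective_risk_term=selective.selective_risk_term,
                         coverage_penalty=selective.coverage_penalty,
                         selective_loss=selective.selective_loss,
                         auxiliary_loss=l_h, total=float(total))


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Decision:
    """Outcome for one sample: a class when selected, rejection otherwise."""

    selected: bool
    predicted_class: str   # one of CLASSES, or REJECT
    g_score: float


@dataclass(frozen=True)
class TrainConfig:
    """Selective-training hyperparameters."""

    target_coverage: float = 0.98
    lam: float = 200.0
    alpha: float = 0.3
    tau: float | None = None       # inference threshold; defaults to coverage
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 300
    lr_patience: int = 10
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_coverage <= 1:
            raise ValueError("target coverage must be in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _SelectiveModel(Module):
    def __init__(self, n_channels: int, rng: np.random.Generator,
                 conv_filters=(32, 64), kernel_size=5, pool=2, lstm_units=64,
                 target_coverage: float = 0.98):
        super().__init__()
        self.pool = pool
        c = n_channels
        convs = []
        for f in conv_filters:
            convs.append(Conv1d(c, f, kernel_size, rng))
            c = f
        self.convs = convs
        self.lstm = LSTM(c, lstm_units, rng)
        self.head_f = Dense(lstm_units, 2, rng)
        self.head_g = Dense(lstm_units, 1, rng)
        self.bn_g = BatchNorm1d(1)
        self.head_h = Dense(lstm_units, 2, rng)
        # start the selection head at its target operating point: batch-norm
        # shift = logit(c), small scale.  The empirical coverage then begins
        # at ~c and the interior-point penalty only has to hold it there,
        # instead of dragging a saturating sigmoid across half its range one
        # Adam-sized step at a time.
        cc = min(max(target_coverage, 0.01), 0.99)
        self.bn_g.beta.data[:] = np.log(cc / (1 - cc))
        self.bn_g.gamma.data[:] = 0.1

    def forward(self, z: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor, ad.Tensor]:
        h = z
        for conv in self.convs:
            h = ad.avg_pool1d(ad.relu(conv(h)), self.pool)
        h = self.lstm(h)
        logits_f = self.head_f(h)
        g = ad.sigmoid(self.bn_g(self.head_g(h)))[:, 0]
        logits_h = self.head_h(h)
        return logits_f, g, logits_h


class SelectiveClassifier(ClassifierMixin, BaseEstimator):
    """Selective apnea/normal classifier with a learned confidence score.

    ``fit`` expects latent features of shape (n, n_steps, n_channels) — or
    flattened (n, n_steps * n_channels) — and string or integer labels.
    ``predict`` returns class labels with ``"reject"`` where the confidence
    score falls below ``tau`` (default: the target coverage).
    """

    def __init__(self, target_coverage=0.98, lam=200.0, alpha=0.3, tau=None,
                 lr=1e-3, batch_size=64, epochs=300, lr_patience=10,
                 min_lr=1e-5, conv_filters=(32, 64), kernel_size=5, pool=2,
                 lstm_units=64, latent_shape=(150, 8), random_state=0,
                 verbose=0):
        self.target_coverage = target_coverage
        self.lam = lam
        self.alpha = alpha
        self.tau = tau
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_patience = lr_patience
        self.min_lr = min_lr
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool = pool
        self.lstm_units = lstm_units
        self.latent_shape = latent_shape
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ----------------------------------------------------------
    def _check_Z(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=np.float32)
        steps, ch = self.latent_shape
        if Z.ndim == 2 and Z.shape[1] == steps * ch:
            Z = Z.reshape(len(Z), steps, ch)
        if Z.ndim != 3 or Z.shape[1:] != (steps, ch):
            raise ValueError(f"expected latents of shape (n, {steps}, {ch})")
        return Z

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        idx = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.array([idx[v] for v in y], dtype=int)
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None

    def _effective_tau(self, tau=None) -> float:
        t = tau if tau is not None else (
            self.tau if self.tau is not None else self.target_coverage)
        if not 0 <= t <= 1:
            raise ValueError("tau must lie in [0, 1]")
        return float(t)

    # -- training ----------------------------------------------------------
    def fit(self, Z, y, Z_val=None, y_val=None):
        Z = self._check_Z(Z)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(np.unique(y).tolist()))
        if len(self.classes_) != 2:
            raise ValueError("selective classifier is two-class")
        yi = self._encode_y(y)
        have_val = Z_val is not None and y_val is not None
        if have_val:
            Z_val = self._check_Z(Z_val)
            yv = self._encode_y(np.asarray(y_val))

        rng = np.random.default_rng(self.random_state)
        self.model_ = _SelectiveModel(Z.shape[2], rng,
                                      conv_filters=tuple(self.conv_filters),
                                      kernel_size=self.kernel_size,
                                      pool=self.pool,
                                      lstm_units=self.lstm_units,
                                      target_coverage=self.target_coverage)
        opt = Adam(self.model_.parameters(), lr=self.lr)
        c, lam, alpha = self.target_coverage, self.lam, self.alpha
        history: list[dict] = []
        best_monitor = np.inf
        best_train = np.inf
        best_state = None
        plateau = 0
        diverged = False
        n = len(Z)
        with ad.pool.active():
            for epoch in range(self.epochs):
                self.model_.train()
                order = rng.permutation(n)
                ep = {"total": [], "l_fg": [], "l_h": [], "coverage": [],
                      "risk": [], "penalty": []}
                for start in range(0, n, self.batch_size):
                    idx = order[start:start + self.batch_size]
                    zb = ad.Tensor(Z[idx])
                    yb = yi[idx]
                    logits_f, g, logits_h = self.model_(zb)
                    ell = ad.softmax_cross_entropy(logits_f, yb)
                    phi = g.mean()
                    risk = (ell * g).mean() / phi
                    penalty = lam * ad.maximum0(ad._const(c) - phi) ** 2
                    l_fg = risk + penalty
                    l_h = ad.softmax_cross_entropy(logits_h, yb).mean()
                    total = alpha * l_fg + (1 - alpha) * l_h
                    if not np.isfinite(total.data):
                        # divergence: stop and fall back to the last good
                        # checkpoint rather than propagate NaN weights
                        if best_state is None:
                            raise RuntimeError(
                                f"non-finite selective loss at epoch {epoch} "
                                "before any usable checkpoint")
                        import warnings as _w
                        _w.warn(f"non-finite selective loss at epoch {epoch}; "
                                "stopping and restoring best checkpoint")
                        diverged = True
                        break
                    opt.zero_grad()
                    total.backward()
                    opt.step()
                    ep["total"].append(float(total.data))
                    ep["l_fg"].append(float(l_fg.data))
                    ep["l_h"].append(float(l_h.data))
                    ep["coverage"].append(float(phi.data))
                    ep["risk"].append(float(risk.data))
                    ep["penalty"].append(float(penalty.data))
                    zb = logits_f = g = logits_h = ell = phi = None
                    risk = penalty = l_fg = l_h = total = None
                    ad.pool.release_all()
                if diverged:
                    break
                rec = {"epoch": epoch, "lr": opt.lr}
                rec.update({k: float(np.mean(v)) for k, v in ep.items()})
                if have_val:
                    vb = self._evaluate_objective(Z_val, yv)
                    rec.update({f"val_{k}": v for k, v in vb.items()})
                monitor = rec["val_total"] if have_val else rec["total"]
                history.append(rec)
                if self.verbose:
                    print(f"[sel] epoch {epoch}: total {rec['total']:.4f} "
                          f"phi {rec['coverage']:.3f} monitor {monitor:.4f}")
                if monitor < best_monitor - 1e-6:
                    best_monitor = monitor
                    best_state = self.model_.state_dict()
                # plateau detection uses the (smooth) training objective; the
                # validation objective at small validation sizes is dominated
                # by coverage-penalty noise
                if rec["total"] < best_train - 1e-6:
                    best_train = rec["total"]
                    plateau = 0
                else:
                    plateau += 1
                    if plateau >= self.lr_patience and opt.lr > self.min_lr:
                        opt.lr = max(self.min_lr, opt.lr / 2)  # halve on plateau
                        plateau = 0
        ad.pool.clear()
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        return self

    def _evaluate_objective(self, Z: np.ndarray, yi: np.ndarray) -> dict:
        """Objective terms over a full (validation) set in eval mode."""
        p_f, g, p_h = self._forward_proba(Z)
        sel = selective_loss(p_f, g, yi, self.target_coverage, self.lam)
        full = combined_loss(sel, p_h, yi, self.alpha)
        return {"total": full.total, "l_fg": full.selective_loss,
                "l_h": full.auxiliary_loss, "coverage": full.coverage,
                "risk": full.selective_risk_term,
                "penalty": full.coverage_penalty}

    # -- inference ---------------------------------------------------------
    def _forward_proba(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        check_is_fitted(self, "model_")
        self.model_.eval()
        ps, gs, hs = [], [], []
        with ad.no_grad(), ad.pool.active():
            for start in range(0, len(Z), self.batch_size):
                zb = ad.Tensor(Z[start:start + self.batch_size])
                logits_f, g, logits_h = self.model_(zb)
                ps.append(ad.softmax(logits_f).data.astype(np.float64))
                gs.append(g.data.astype(np.float64))
                hs.append(ad.softmax(logits_h).data.astype(np.float64))
                zb = logits_f = g = logits_h = None
                ad.pool.release_all()
        self.model_.train()
        return np.concatenate(ps), np.concatenate(gs), np.concatenate(hs)

    def predict_proba(self, Z) -> np.ndarray:
        """Prediction-head class probabilities, columns follow ``classes_``."""
        return self._forward_proba(self._check_Z(Z))[0]

    def confidence_scores(self, Z) -> np.ndarray:
        """Selection-head confidence g(x) in [0, 1] per sample."""
        return self._forward_proba(self._check_Z(Z))[1]

    def auxiliary_proba(self, Z) -> np.ndarray:
        return self._forward_proba(self._check_Z(Z))[2]

    def embeddings(self, Z) -> np.ndarray:
        """Shared-body activations (the LSTM's final hidden state) per
        sample — the representation the heads read; exportable for external
        2-D visualisation."""
        check_is_fitted(self, "model_")
        self.model_.eval()
        Z = self._check_Z(Z)
        outs = []
        with ad.no_grad(), ad.pool.active():
            for start in range(0, len(Z), self.batch_size):
                h = ad.Tensor(Z[start:start + self.batch_size])
                for conv in self.model_.convs:
                    h = ad.avg_pool1d(ad.relu(conv(h)), self.model_.pool)
                h = self.model_.lstm(h)
                outs.append(h.data.copy())
                h = None
                ad.pool.release_all()
        self.model_.train()
        return np.concatenate(outs)

    def decide(self, Z, tau: float | None = None) -> list[Decision]:
        """Selective prediction: the class of f where g >= tau, else reject.

        Probability ties break toward apnea (sensitivity first).
        """
        Z = self._check_Z(Z)
        tau = self._effective_tau(tau)
        p_f, g, _ = self._forward_proba(Z)
        # argmax with ties to the apnea column
        ai = int(np.where(self.classes_ == "apnea")[0][0]) \
            if "apnea" in self.classes_ else 0
        out = []
        for pi, gi in zip(p_f, g):
            selected = bool(gi >= tau)
            if not selected:
                out.append(Decision(False, REJECT, float(gi)))
                continue
            best = int(np.argmax(pi))
            if pi[best] == pi[ai]:
                best = ai
            out.append(Decision(True, str(self.classes_[best]), float(gi)))
        return out

    def predict(self, Z, tau: float | None = None) -> np.ndarray:
        return np.array([d.predicted_class for d in self.decide(Z, tau)],
                        dtype=object)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "model_")
        path = Path(path)
        state = self.model_.state_dict()
        state["__classes__"] = np.asarray(self.classes_, dtype="U16")
        np.savez_compressed(path, **state)
        path.with_suffix(".json").write_text(json.dumps(self.get_params(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SelectiveClassifier":
        path = Path(path)
        params = json.loads(path.with_suffix(".json").read_text())
        for key in ("conv_filters", "latent_shape"):
            params[key] = tuple(params[key])
        est = cls(**params)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            state = {k: z[k] for k in z.files}
        est.classes_ = np.asarray(state.pop("__classes__"))
        rng = np.random.default_rng(est.random_state)
        est.model_ = _SelectiveModel(est.latent_shape[1], rng,
                                     conv_filters=tuple(est.conv_filters),
                                     kernel_size=est.kernel_size,
                                     pool=est.pool, lstm_units=est.lstm_units,
                                     target_coverage=est.target_coverage)
        est.model_.load_state_dict(state)
        est.history_ = pd.DataFrame()
        est.n_epochs_ = 0
        return est


# ---------------------------------------------------------------------------
# thin functional surface
# ---------------------------------------------------------------------------

def build_selective_model(latent_shape=(150, 8), config: TrainConfig | None = None,
                          **overrides) -> SelectiveClassifier:
    cfg = config or TrainConfig()
    kwargs = dict(target_coverage=cfg.target_coverage, lam=cfg.lam,
                  alpha=cfg.alpha, tau=cfg.tau, lr=cfg.lr,
                  batch_size=cfg.batch_size, epochs=cfg.epochs,
                  lr_patience=cfg.lr_patience, min_lr=cfg.min_lr,
                  latent_shape=tuple(latent_shape), random_state=cfg.seed)
    kwargs.update(overrides)
    return SelectiveClassifier(**kwargs)


def train_selective(model: SelectiveClassifier, Z, y, Z_val=None, y_val=None
                    ) -> SelectiveClassifier:
    return model.fit(Z, y, Z_val=Z_val, y_val=y_val)


def predict_with_rejection(model: SelectiveClassifier, Z,
                           tau: float | None = None) -> list[Decision]:
    return model.decide(Z, tau)
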