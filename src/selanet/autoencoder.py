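"""Temporal-convolutional-network autoencoder for segment compression.

The encoder runs a causal dilated TCN stack (one residual block per dilation
rate 1, 2, 4, 8, 16; 10 filters each) over the full-resolution two-channel
segment, average-pools time by 8 then by 5 (6000 -> 150 steps) and applies a
kernel-1 convolution with 8 filters, giving a (150, 8) latent — 1,200 numbers
for 12,000 input samples, a fixed 10:1 compression.  The decoder repeats each
latent step 40 times, runs a second TCN stack and projects back to the two
channels.  Training minimises mean squared reconstruction error with Adam.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .nn import autodiff as ad
from .nn.layers import Conv1d, Module, TCNStack
from .nn.optim import Adam


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder architecture and optimisation settings."""

    dilations: tuple[int, ...] = (1, 2, 4, 8, 16)
    n_filters: int = 10
    bottleneck_filters: int = 8
    bottleneck_kernel: int = 1
    kernel_size: int = 3
    pool_factors: tuple[int, int] = (8, 5)   # 6000 -> 750 -> 150
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 10
    seed: int = 0

    @property
    def downsample_factor(self) -> int:
        return int(np.prod(self.pool_factors))


class _AEModel(Module):
    def __init__(self, cfg: AEConfig, rng: np.random.Generator, n_channels: int = 2):
        super().__init__()
        self.cfg = cfg
        self.enc_tcn = TCNStack(n_channels, cfg.n_filters, cfg.kernel_size,
                                cfg.dilations, rng)
        self.enc_proj = Conv1d(cfg.n_filters, cfg.bottleneck_filters,
                               cfg.bottleneck_kernel, rng)
        self.dec_tcn = TCNStack(cfg.bottleneck_filters, cfg.n_filters,
                                cfg.kernel_size, cfg.dilations, rng)
        self.dec_proj = Conv1d(cfg.n_filters, n_channels, 1, rng)

    def encode(self, x: ad.Tensor) -> ad.Tensor:
        h = self.enc_tcn(x)
        for m in self.cfg.pool_factors:
            h = ad.avg_pool1d(h, m)
        return self.enc_proj(h)

    def decode(self, z: ad.Tensor) -> ad.Tensor:
        h = ad.upsample_repeat(z, self.cfg.downsample_factor)
        return self.dec_proj(self.dec_tcn(h))

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        return self.decode(self.encode(x))


def _as_channels_last(X: np.ndarray) -> np.ndarray:
    """Accept (n, 2, L) segment stacks; return float32 (n, L, 2)."""
    X = np.asarray(X)
    if X.ndim != 3 or X.shape[1] != 2:
        raise ValueError(f"expected (n, 2, L) segment array, got {X.shape}")
    return np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)


class TCNAutoencoder(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator wrapping the TCN autoencoder.

    ``fit`` trains on stacked segments of shape (n, 2, L) with L divisible by
    the 40x downsampling factor; ``transform`` returns (n, 150, 8) latents
    when L = 6000.

    Parameters mirror :class:`AEConfig`; fitted attributes carry a trailing
    underscore (``model_``, ``history_``, ``n_epochs_``).
    """

    def __init__(self, dilations=(1, 2, 4, 8, 16), n_filters=10,
                 bottleneck_filters=8, bottleneck_kernel=1, kernel_size=3,
                 pool_factors=(8, 5), epochs=100, batch_size=32, lr=1e-3,
                 patience=10, random_state=0, verbose=0):
        self.dilations = dilations
        self.n_filters = n_filters
        self.bottleneck_filters = bottleneck_filters
        self.bottleneck_kernel = bottleneck_kernel
        self.kernel_size = kernel_size
        self.pool_factors = pool_factors
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # -- construction ------------------------------------------------------
    def _config(self) -> AEConfig:
        return AEConfig(dilations=tuple(self.dilations), n_filters=self.n_filters,
                        bottleneck_filters=self.bottleneck_filters,
                        bottleneck_kernel=self.bottleneck_kernel,
                        kernel_size=self.kernel_size,
                        pool_factors=tuple(self.pool_factors),
                        epochs=self.epochs, batch_size=self.batch_size,
                        lr=self.lr, patience=self.patience,
                        seed=self.random_state)

    def _build(self, seq_len: int) -> None:
        cfg = self._config()
        if seq_len % cfg.downsample_factor != 0:
            raise ValueError(
                f"segment length {seq_len} not divisible by the "
                f"{cfg.downsample_factor}x downsampling factor")
        rng = np.random.default_rng(self.random_state)
        self.model_ = _AEModel(cfg, rng)

    # -- training ----------------------------------------------------------
    def fit(self, X, y=None, X_val=None):
        Xcl = _as_channels_last(X)
        self._build(Xcl.shape[1])
        Xv = _as_channels_last(X_val) if X_val is not None else None
        rng = np.random.default_rng(self.random_state + 1)
        opt = Adam(self.model_.parameters(), lr=self.lr)
        history: list[dict] = []
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        n = len(Xcl)
        with ad.pool.active():
            for epoch in range(self.epochs):
                self.model_.train()
                order = rng.permutation(n)
                losses = []
                for start in range(0, n, self.batch_size):
                    idx = order[start:start + self.batch_size]
                    xb = ad.Tensor(Xcl[idx])
                    recon = self.model_(xb)
                    loss = ((recon - xb) ** 2).mean()
                    if not np.isfinite(loss.data):
                        raise RuntimeError(
                            f"non-finite reconstruction loss at epoch {epoch}")
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    losses.append(float(loss.data))
                    xb = recon = loss = None
                    ad.pool.release_all()
                train_mse = float(np.mean(losses))
                val_mse = (self.reconstruction_mse(X_val) if Xv is not None
                           else train_mse)
                history.append({"epoch": epoch, "train_mse": train_mse,
                                "val_mse": val_mse})
                if self.verbose:
                    print(f"[ae] epoch {epoch}: train {train_mse:.5f} "
                          f"val {val_mse:.5f}")
                if val_mse < best_val - 1e-7:
                    best_val = val_mse
                    best_state = self.model_.state_dict()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break
        ad.pool.clear()
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        self.best_val_mse_ = best_val if best_state is not None else None
        return self

    # -- inference ---------------------------------------------------------
    def _batched(self, X: np.ndarray, fn) -> np.ndarray:
        outs = []
        with ad.no_grad(), ad.pool.active():
            for start in range(0, len(X), self.batch_size):
                out = fn(ad.Tensor(X[start:start + self.batch_size]))
                outs.append(out.data.copy())
                out = None
                ad.pool.release_all()
        return np.concatenate(outs, axis=0)

    def transform(self, X) -> np.ndarray:
        """Encode segments to (n, n_steps, bottleneck_filters) latents."""
        check_is_fitted(self, "model_")
        self.model_.eval()
        return self._batched(_as_channels_last(X), self.model_.encode)

    def inverse_transform(self, Z) -> np.ndarray:
        """Decode latents back to (n, 2, L) signal space."""
        check_is_fitted(self, "model_")
        self.model_.eval()
        Z = np.asarray(Z, dtype=np.float32)
        out = self._batched(Z, self.model_.decode)
        return out.transpose(0, 2, 1)

    def reconstruct(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        out = self._batched(_as_channels_last(X), self.model_)
        return out.transpose(0, 2, 1)

    def reconstruction_mse(self, X) -> float:
        return float(np.mean((self.reconstruct(X) - np.asarray(X)) ** 2))

    def score(self, X, y=None) -> float:
        return -self.reconstruction_mse(X)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "model_")
        path = Path(path)
        np.savez_compressed(path, **self.model_.state_dict())
        path.with_suffix(".json").write_text(
            json.dumps(asdict(self._config()), indent=1))

    @classmethod
    def load(cls, path: str | Path, seq_len: int = 6000) -> "TCNAutoencoder":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        est = cls(dilations=tuple(cfg["dilations"]), n_filters=cfg["n_filters"],
                  bottleneck_filters=cfg["bottleneck_filters"],
                  bottleneck_kernel=cfg["bottleneck_kernel"],
                  kernel_size=cfg["kernel_size"],
                  pool_factors=tuple(cfg["pool_factors"]), epochs=cfg["epochs"],
                  batch_size=cfg["batch_size"], lr=cfg["lr"],
                  patience=cfg["patience"], random_state=cfg["seed"])
        est._build(seq_len)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            est.model_.load_state_dict({k: z[k] for k in z.files})
        est.history_ = pd.DataFrame()
        est.n_epochs_ = 0
        return est


# ---------------------------------------------------------------------------
# thin functional surface
# ---------------------------------------------------------------------------

def build_autoencoder(config: AEConfig | None = None, **overrides) -> TCNAutoencoder:
    cfg = config or AEConfig()
    kwargs = dict(dilations=cfg.dilations, n_filters=cfg.n_filters,
                  bottleneck_filters=cfg.bottleneck_filters,
                  bottleneck_kernel=cfg.bottleneck_kernel,
                  kernel_size=cfg.kernel_size, pool_factors=cfg.pool_factors,
                  epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
                  patience=cfg.patience, random_state=cfg.seed)
    kwargs.update(overrides)
    return TCNAutoencoder(**kwargs)


def train_autoencoder(model: TCNAutoencoder, X_train, X_val=None) -> TCNAutoencoder:
    return model.fit(X_train, X_val=X_val)


def encode_dataset(model: TCNAutoencoder, X) -> np.ndarray:
    """One (n_steps, n_latent_channels) feature per segment, order preserved."""
    return model.transform(X)


def reconstruction_correlation(model: TCNAutoencoder, X) -> float:
    """Mean Pearson correlation between original and reconstructed segments.

    Computed per segment-channel; channels with zero variance on either side
    are skipped with a warning (correlation undefined there).
    """
    X = np.asarray(X, dtype=np.float64)
    R = model.reconstruct(X).astype(np.float64)
    rs = []
    skipped = 0
    for i in range(X.shape[0]):
        for ch in range(X.shape[1]):
            a, b = X[i, ch], R[i, ch]
            if a.std() == 0 or b.std() == 0:
                skipped += 1
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
    if skipped:
        warnings.warn(f"skipped {skipped} constant segment-channels in "
                      "correlation analysis")
    if not rs:
        raise ValueError("no non-constant segment-channels to correlate")
    return float(np.mean(rs))
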