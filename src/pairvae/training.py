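"""Mini-batch training of the shared-latent model, deterministic under a seed.

One integer seed governs weight initialization, the validation split,
epoch shuffles, dropout masks and the reparameterization noise, so two
runs with identical inputs produce identical loss histories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_core as mc
from ._nn import Adam
from .io_preprocess import PairedDataset

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "FittedModel", "TrainingError", "fit", "transform",
           "save_model", "load_model"]


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 100
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0
    validation_fraction: float = 0.1
    clip_norm: float | None = None  # gradient clipping, off by default

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch norm needs batch statistics)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5]")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class FittedModel:
    spec: mc.ModelSpec
    inference: mc.InferenceParams
    generative: mc.GenerativeParams
    history: pd.DataFrame
    epochs_run: int

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        return transform(self, x_new)


def _as_dense(M) -> np.ndarray:
    import scipy.sparse as sp

    return np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)


def _train_step(x, y, inf, gen, lam, rng, optimizer):
    """One forward/backward/update pass; returns the batch LossBreakdown."""
    b = x.shape[0]
    try:
        loss, code, xhat, yhat = mc.elbo_objective(x, y, inf, gen, lam, rng=rng, training=True)
    except (ValueError, FloatingPointError) as exc:
        # diverged weights surface as non-finite activations mid-forward
        raise TrainingError("non-finite objective") from exc
    if not np.isfinite(loss.objective):
        raise TrainingError("non-finite objective")

    # reconstruction gradients flow through both decoders into z
    g_z = gen.decoder_x.backward(lam * 2.0 * (xhat - x) / b)
    g_z += gen.decoder_y.backward(lam * 2.0 * (yhat - y) / b)

    # z = mu + exp(logvar/2) * eps
    std = np.exp(0.5 * code.logvar)
    eps = (code.sample - code.mu) / std
    g_mu = g_z + code.mu / b
    g_logvar = g_z * 0.5 * std * eps + 0.5 * (np.exp(code.logvar) - 1.0) / b

    g_h = inf.head_mu.backward(g_mu) + inf.head_logvar.backward(g_logvar)
    inf.trunk.backward(g_h)
    optimizer.step()
    return loss


def _epoch_objective(x, y, inf, gen, lam, rng, batch_size) -> mc.LossBreakdown:
    """Evaluation-mode single-draw objective over a full data split."""
    parts, weights = [], []
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start:start + batch_size], y[start:start + batch_size]
        loss, *_ = mc.elbo_objective(xb, yb, inf, gen, lam, rng=rng, training=False)
        parts.append(loss)
        weights.append(xb.shape[0])
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    return mc.LossBreakdown(
        kl=float(sum(p.kl * wi for p, wi in zip(parts, w))),
        recon_x=float(sum(p.recon_x * wi for p, wi in zip(parts, w))),
        recon_y=float(sum(p.recon_y * wi for p, wi in zip(parts, w))),
        objective=float(sum(p.objective * wi for p, wi in zip(parts, w))),
    )


def fit(data: PairedDataset, spec: mc.ModelSpec, config: TrainConfig = TrainConfig()) -> FittedModel:
    """Fit encoder and decoders by adaptive-moment SGD on the weighted ELBO.

    Early-stops when the validation objective has not improved for
    ``config.patience`` epochs and returns the best-validation-epoch
    parameters. With ``validation_fraction=0`` the training objective is
    used for stopping instead.
    """
    X = _as_dense(data.X)
    Y = _as_dense(data.Y)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data contain non-finite values; preprocess first")
    n = X.shape[0]
    if X.shape[1] != spec.input_dim_x or Y.shape[1] != spec.input_dim_y:
        raise ValueError(
            f"data dims ({X.shape[1]}, {Y.shape[1]}) do not match spec "
            f"({spec.input_dim_x}, {spec.input_dim_y})"
        )
    if config.batch_size > n:
        raise ValueError(f"batch_size={config.batch_size} exceeds n={n}")
    if n < 2 * config.batch_size:
        warnings.warn(f"n={n} is small relative to batch_size={config.batch_size}",
                      stacklevel=2)

    inf, gen = mc.build_networks(spec)
    rng = np.random.default_rng(config.seed)

    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[train_idx], Y[train_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    optimizer = Adam(inf.modules() + gen.modules(), lr=config.learning_rate,
                     clip_norm=config.clip_norm)
    lam = spec.lambda_weight

    best_obj = np.inf
    best_state = mc.get_state(inf, gen)
    best_epoch = 0
    stall = 0
    rows = []

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        batch_losses, batch_sizes = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm cannot use a singleton batch
            try:
                loss = _train_step(X_tr[idx], Y_tr[idx], inf, gen, lam, rng, optimizer)
            except TrainingError:
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}; "
                    "try a lower learning rate"
                ) from None
            batch_losses.append(loss)
            batch_sizes.append(len(idx))

        w = np.asarray(batch_sizes, dtype=float)
        w /= w.sum()
        train_loss = {
            k: float(sum(getattr(l, k) * wi for l, wi in zip(batch_losses, w)))
            for k in ("kl", "recon_x", "recon_y", "objective")
        }
        if n_val:
            val = _epoch_objective(X_val, Y_val, inf, gen, lam, rng, config.batch_size)
            monitor = val.objective
        else:
            val = None
            monitor = train_loss["objective"]
        rows.append({"epoch": epoch, **train_loss,
                     "val_objective": val.objective if val else np.nan})

        if monitor < best_obj - 1e-9:
            best_obj = monitor
            best_state = mc.get_state(inf, gen)
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                break

    mc.set_state(inf, gen, best_state)
    history = pd.DataFrame(rows)
    return FittedModel(spec=spec, inference=inf, generative=gen,
                       history=history, epochs_run=len(rows))


def transform(model: FittedModel, x_new: np.ndarray) -> np.ndarray:
    """Posterior means for new cells: the deterministic embedding (m x d)."""
    x_new = _as_dense(x_new)
    if x_new.ndim != 2 or x_new.shape[1] != model.spec.input_dim_x:
        raise ValueError(
            f"expected (m, {model.spec.input_dim_x}) input, got {x_new.shape}"
        )
    code = mc.encode(x_new, model.inference, training=False, rng=None)
    return code.mu


def save_model(model: FittedModel, path) -> None:
    path = Path(path)
    mc.save_checkpoint(path, model.spec, model.inference, model.generative)
    model.history.to_csv(path / "history.csv", index=False)


def load_model(path) -> FittedModel:
    path = Path(path)
    spec, inf, gen = mc.load_checkpoint(path)
    hist_path = path / "history.csv"
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return FittedModel(spec=spec, inference=inf, generative=gen,
                       history=history, epochs_run=len(history))
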