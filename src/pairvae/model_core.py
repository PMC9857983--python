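"""Shared-latent generative model for paired two-modality data.

A single low-dimensional latent code per cell generates both observed
modalities through modality-specific decoders; an encoder reading only
modality X produces a diagonal-Gaussian approximate posterior. The loss
is a weighted negative evidence lower bound: a KL regularizer toward the
standard-normal prior plus ``lambda_weight`` times the Gaussian
reconstruction errors of both modalities, estimated with a single
reparameterized draw per cell.

All functions here are pure given a generator: no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import Adam, BatchNormCenter, Dense, Dropout, ReLU, Sequential, mlp_stack

__all__ = [
    "ModelSpec",
    "InferenceParams",
    "GenerativeParams",
    "LatentCode",
    "LossBreakdown",
    "build_networks",
    "encode",
    "decode",
    "kl_term",
    "recon_term",
    "elbo_objective",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to rebuild the networks deterministically.

    ``decoder_widths`` are the hidden widths between the latent and the
    output layer (latent -> 32 -> 64 -> 128 -> output by default); the
    encoder mirrors them in reverse. An empty tuple yields purely affine
    encoder/decoders — the linear variant used as an analytic test hook.
    """

    d: int
    input_dim_x: int
    input_dim_y: int
    decoder_widths: tuple[int, ...] = (32, 64, 128)
    dropout_rate: float = 0.05
    lambda_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"latent dimensionality must be >= 1, got {self.d}")
        if self.input_dim_x < 1 or self.input_dim_y < 1:
            raise ValueError("input dimensions must be positive")
        if any(w <= 0 for w in self.decoder_widths):
            raise ValueError(f"nonpositive decoder width in {self.decoder_widths}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.lambda_weight < 0:
            raise ValueError(f"lambda_weight must be >= 0, got {self.lambda_weight}")
        object.__setattr__(self, "decoder_widths", tuple(self.decoder_widths))

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(reversed(self.decoder_widths))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)
        raw["decoder_widths"] = tuple(raw["decoder_widths"])
        return cls(**raw)


@dataclass
class InferenceParams:
    """Encoder trunk plus the two affine heads producing mu and logvar."""

    trunk: Sequential
    head_mu: Sequential
    head_logvar: Sequential

    def modules(self):
        return [self.trunk, self.head_mu, self.head_logvar]


@dataclass
class GenerativeParams:
    """The two modality-specific decoders; residual noise scale is fixed."""

    decoder_x: Sequential
    decoder_y: Sequential
    sigma: float = 1.0

    def modules(self):
        return [self.decoder_x, self.decoder_y]


@dataclass
class LatentCode:
    """Posterior parameters and one reparameterized draw per cell."""

    mu: np.ndarray
    logvar: np.ndarray
    sample: np.ndarray


@dataclass
class LossBreakdown:
    kl: float
    recon_x: float
    recon_y: float
    objective: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _decoder(spec: ModelSpec, out_dim: int, rng: np.random.Generator) -> Sequential:
    widths = (spec.d, *spec.decoder_widths)
    layers = mlp_stack(widths, spec.dropout_rate, rng)
    layers.append(Dense(widths[-1], out_dim, rng))  # affine output, identity activation
    return Sequential(layers)


def build_networks(spec: ModelSpec) -> tuple[InferenceParams, GenerativeParams]:
    """Instantiate encoder and decoders with seed-deterministic weights."""
    rng = np.random.default_rng(spec.seed)
    decoder_x = _decoder(spec, spec.input_dim_x, rng)
    decoder_y = _decoder(spec, spec.input_dim_y, rng)
    trunk_widths = (spec.input_dim_x, *spec.encoder_widths)
    trunk = Sequential(mlp_stack(trunk_widths, spec.dropout_rate, rng))
    head_mu = Sequential([Dense(trunk_widths[-1], spec.d, rng)])
    head_logvar = Sequential([Dense(trunk_widths[-1], spec.d, rng)])
    return InferenceParams(trunk, head_mu, head_logvar), GenerativeParams(decoder_x, decoder_y)


def encode(
    x_batch: np.ndarray,
    params: InferenceParams,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> LatentCode:
    """Map a (batch, p) matrix to posterior mu/logvar and one draw.

    Evaluation mode (the default) uses running batch-norm statistics and
    no dropout; with no generator supplied the draw equals ``mu``.
    """
    x_batch = np.asarray(x_batch, dtype=float)
    if not np.all(np.isfinite(x_batch)):
        raise ValueError("encoder input contains non-finite values")
    h = params.trunk.forward(x_batch, training=training, rng=rng)
    mu = params.head_mu.forward(h, training=training, rng=rng)
    logvar = params.head_logvar.forward(h, training=training, rng=rng)
    if rng is None:
        sample = mu.copy()
    else:
        eps = rng.standard_normal(mu.shape)
        sample = mu + np.exp(0.5 * logvar) * eps
    return LatentCode(mu=mu, logvar=logvar, sample=sample)


def decode(
    z: np.ndarray,
    params: GenerativeParams,
    modality: str,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reconstruction means ``f_x(z)`` or ``f_y(z)``."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent input contains non-finite values")
    if modality == "x":
        net = params.decoder_x
    elif modality == "y":
        net = params.decoder_y
    else:
        raise ValueError(f"modality must be 'x' or 'y', got {modality!r}")
    return net.forward(z, training=training, rng=rng)


def kl_term(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean-over-cells KL of N(mu, diag exp(logvar)) from N(0, I).

    Closed form per cell: 0.5 * sum_j (mu_j^2 + exp(logvar_j) - 1 - logvar_j).
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: mu {mu.shape} vs logvar {logvar.shape}")
    per_cell = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=-1)
    return float(np.mean(per_cell))


def recon_term(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean-over-cells squared Euclidean distance between rows.

    This is the Gaussian negative log-likelihood with unit noise scale,
    additive constants dropped.
    """
    observed = np.asarray(observed, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if observed.shape != reconstructed.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs reconstructed {reconstructed.shape}"
        )
    return float(np.mean(np.sum((observed - reconstructed) ** 2, axis=-1)))


def elbo_objective(
    x_batch: np.ndarray,
    y_batch: np.ndarray,
    inf: InferenceParams,
    gen: GenerativeParams,
    lambda_weight: float,
    *,
    rng: np.random.Generator,
    training: bool = False,
) -> tuple[LossBreakdown, LatentCode, np.ndarray, np.ndarray]:
    """Single-draw estimate of the weighted negative ELBO.

    Returns the loss breakdown together with the latent code and both
    reconstructions so a training step can reuse the forward pass.
    """
    if lambda_weight < 0:
        raise ValueError(f"lambda_weight must be >= 0, got {lambda_weight}")
    code = encode(x_batch, inf, training=training, rng=rng)
    xhat = decode(code.sample, gen, "x", training=training, rng=rng)
    yhat = decode(code.sample, gen, "y", training=training, rng=rng)
    kl = kl_term(code.mu, code.logvar)
    rx = recon_term(x_batch, xhat)
    ry = recon_term(y_batch, yhat)
    loss = LossBreakdown(kl=kl, recon_x=rx, recon_y=ry,
                         objective=kl + lambda_weight * (rx + ry))
    return loss, code, xhat, yhat


# ---------------------------------------------------------------------------
# checkpointing

def _state_arrays(inf: InferenceParams, gen: GenerativeParams) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    named = [("enc", inf.trunk), ("mu", inf.head_mu), ("lv", inf.head_logvar),
             ("dx", gen.decoder_x), ("dy", gen.decoder_y)]
    for tag, mod in named:
        for i, layer in enumerate(mod.layers):
            for pname, val in layer.params.items():
                out[f"{tag}.{i}.{pname}"] = val
            if isinstance(layer, BatchNormCenter):
                out[f"{tag}.{i}.running_mean"] = layer.running_mean
                out[f"{tag}.{i}.running_var"] = layer.running_var
    return out


def get_state(inf: InferenceParams, gen: GenerativeParams) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in _state_arrays(inf, gen).items()}


def set_state(inf: InferenceParams, gen: GenerativeParams, state: dict[str, np.ndarray]) -> None:
    slots = _state_arrays(inf, gen)
    if set(slots) != set(state):
        raise ValueError("checkpoint state does not match network structure")
    named = {"enc": inf.trunk, "mu": inf.head_mu, "lv": inf.head_logvar,
             "dx": gen.decoder_x, "dy": gen.decoder_y}
    for key, val in state.items():
        tag, idx, pname = key.split(".")
        layer = named[tag].layers[int(idx)]
        if pname in ("running_mean", "running_var"):
            setattr(layer, pname, np.array(val, dtype=float))
        else:
            layer.params[pname] = np.array(val, dtype=float)


def save_checkpoint(path, spec: ModelSpec, inf: InferenceParams, gen: GenerativeParams) -> None:
    """Write a directory with a JSON spec and one binary weights file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "model_spec.json").write_text(spec.to_json())
    np.savez(path / "weights.npz", **_state_arrays(inf, gen))


def load_checkpoint(path) -> tuple[ModelSpec, InferenceParams, GenerativeParams]:
    """Rebuild networks from a checkpoint; forward pass is bit-identical."""
    path = Path(path)
    spec = ModelSpec.from_json((path / "model_spec.json").read_text())
    inf, gen = build_networks(spec)
    with np.load(path / "weights.npz") as npz:
        set_state(inf, gen, dict(npz))
    return spec, inf, gen
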