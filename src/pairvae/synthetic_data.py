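"""Paired two-modality data simulator with known shared latent structure.

Cells receive a latent vector drawn either from a Gaussian mixture with
cluster structure or from a one-dimensional gradient (trajectory mode).
Each modality observes the latent through its own fixed random map
(affine or a two-layer tanh network) plus isotropic Gaussian noise, so
the generated data match the generative assumptions of the model and
serve as the parameter-recovery ground truth for acceptance runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .io_preprocess import PairedDataset

__all__ = ["SimConfig", "simulate_paired", "write_fixture"]

_TANH_HIDDEN = 64


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 1000
    d_true: int = 2
    n_clusters: int = 3
    p: int = 50
    q: int = 20
    separation: float = 5.0
    noise_sd: float = 0.5
    nonlinearity: str = "linear"  # or "tanh-mlp"
    trajectory: bool = False
    count_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > self.n_cells:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n_cells={self.n_cells}")
        if self.d_true > min(self.p, self.q):
            raise ValueError("d_true must not exceed min(p, q)")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in ("linear", "tanh-mlp"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


def _modality_map(d: int, out_dim: int, kind: str, rng: np.random.Generator):
    if kind == "linear":
        W = rng.normal(0.0, 1.0, size=(d, out_dim)) / np.sqrt(d)
        b = rng.normal(0.0, 0.1, size=out_dim)
        return lambda z: z @ W + b
    W1 = rng.normal(0.0, 1.0, size=(d, _TANH_HIDDEN)) / np.sqrt(d)
    b1 = rng.normal(0.0, 0.5, size=_TANH_HIDDEN)
    W2 = rng.normal(0.0, 1.0, size=(_TANH_HIDDEN, out_dim)) / np.sqrt(_TANH_HIDDEN)
    b2 = rng.normal(0.0, 0.1, size=out_dim)
    return lambda z: np.tanh(z @ W1 + b1) @ W2 + b2


def _latent_clusters(cfg: SimConfig, rng: np.random.Generator):
    centers = rng.normal(0.0, cfg.separation, size=(cfg.n_clusters, cfg.d_true))
    # balanced assignment guarantees every cluster is nonempty
    labels = np.resize(np.arange(cfg.n_clusters), cfg.n_cells)
    rng.shuffle(labels)
    z = centers[labels] + rng.standard_normal((cfg.n_cells, cfg.d_true))
    return z, labels


def _latent_trajectory(cfg: SimConfig, rng: np.random.Generator):
    t = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    direction = rng.standard_normal(cfg.d_true)
    direction /= np.linalg.norm(direction)
    z = np.outer(t - 0.5, direction) * 2.0 * cfg.separation
    z += 0.1 * rng.standard_normal((cfg.n_cells, cfg.d_true))
    return z, t


def simulate_paired(config: SimConfig):
    """Generate a PairedDataset plus its generating latent and annotation.

    Returns ``(dataset, true_latent, annotation)`` where ``annotation`` is
    integer cluster labels, or the true 1-D position in trajectory mode.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if config.trajectory:
        z, annotation = _latent_trajectory(config, rng)
    else:
        z, annotation = _latent_clusters(config, rng)

    f_x = _modality_map(config.d_true, config.p, config.nonlinearity, rng)
    f_y = _modality_map(config.d_true, config.q, config.nonlinearity, rng)
    X = f_x(z) + config.noise_sd * rng.standard_normal((config.n_cells, config.p))
    Y = f_y(z) + config.noise_sd * rng.standard_normal((config.n_cells, config.q))

    if config.count_mode:
        # map reals to Poisson rates so preprocessing sees integer counts
        X = rng.poisson(np.exp(X / max(X.std(), 1e-8))).astype(float)
        Y = rng.poisson(np.exp(Y / max(Y.std(), 1e-8))).astype(float)

    n = config.n_cells
    data = PairedDataset(
        X=X,
        Y=Y,
        cell_ids=np.array([f"cell{i:05d}" for i in range(n)], dtype=object),
        feature_ids_x=np.array([f"gene{j:04d}" for j in range(config.p)], dtype=object),
        feature_ids_y=np.array([f"feat{j:04d}" for j in range(config.q)], dtype=object),
        labels=None if config.trajectory else annotation.astype(object),
    )
    return data, z, annotation


def _write_mtx_modality(dirpath: Path, M, barcodes, features) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(M)
    if np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(int)
    mmwrite(dirpath / "matrix.mtx", mat)
    pd.Series(barcodes).to_csv(dirpath / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.Series(features).to_csv(dirpath / "features.tsv", sep="\t", header=False, index=False)


def write_fixture(dataset: PairedDataset, dirpath, format: str = "mtx",
                  config: SimConfig | None = None) -> dict:
    """Write both modalities plus ids and labels; returns a manifest dict.

    ``mtx`` writes one matrix.mtx/features.tsv/barcodes.tsv triplet per
    modality (subdirectories ``x/`` and ``y/``); ``csv`` writes one
    delimited file per modality. Round-tripping through ``read_paired``
    reproduces counts exactly and reals to ~1e-12.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        _write_mtx_modality(dirpath / "x", dataset.X, dataset.cell_ids, dataset.feature_ids_x)
        _write_mtx_modality(dirpath / "y", dataset.Y, dataset.cell_ids, dataset.feature_ids_y)
        paths = {"x": str(dirpath / "x"), "y": str(dirpath / "y")}
    elif format == "csv":
        for tag, M, feats in (("x", dataset.X, dataset.feature_ids_x),
                              ("y", dataset.Y, dataset.feature_ids_y)):
            arr = np.asarray(M.todense() if sp.issparse(M) else M)
            pd.DataFrame(arr, index=dataset.cell_ids, columns=feats).to_csv(
                dirpath / f"{tag}.csv", float_format="%.17g")
        paths = {"x": str(dirpath / "x.csv"), "y": str(dirpath / "y.csv")}
    else:
        raise ValueError(f"unknown fixture format {format!r}")

    if dataset.labels is not None:
        pd.DataFrame({"cell_id": dataset.cell_ids, "label": dataset.labels}).to_csv(
            dirpath / "labels.csv", index=False)
    if config is not None:
        (dirpath / "sim_config.json").write_text(config.to_json())

    n, p, q = dataset.shapes
    manifest = {"n": n, "p": p, "q": q, "format": format, "paths": paths}
    (dirpath / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
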