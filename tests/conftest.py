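import dataclasses

import numpy as np
import pytest

import pairvae as pv
from pairvae.io_preprocess import PairedDataset, scale_unit


def make_paired(X, Y, labels=None):
    """Build a PairedDataset from raw arrays with generated ids."""
    X, Y = np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
    n = X.shape[0]
    return PairedDataset(
        X=X,
        Y=Y,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        feature_ids_x=np.array([f"gx{j}" for j in range(X.shape[1])], dtype=object),
        feature_ids_y=np.array([f"gy{j}" for j in range(Y.shape[1])], dtype=object),
        labels=labels,
    )


def scaled(data):
    return dataclasses.replace(data, X=scale_unit(data.X), Y=scale_unit(data.Y))


@pytest.fixture(scope="session")
def cluster3_fixture():
    """Small linear 3-cluster dataset, already scaled, with ground truth."""
    cfg = pv.SimConfig(n_cells=450, d_true=2, n_clusters=3, p=25, q=12,
                       separation=5.0, noise_sd=0.3, seed=42)
    data, z_true, labels = pv.simulate_paired(cfg)
    return scaled(data), z_true, labels


@pytest.fixture(scope="session")
def fitted_small(cluster3_fixture):
    """A quick fit on the 3-cluster fixture, shared across tests."""
    data, z_true, labels = cluster3_fixture
    spec = pv.ModelSpec(d=4, input_dim_x=25, input_dim_y=12,
                        decoder_widths=(16,), lambda_weight=1.0, seed=3)
    config = pv.TrainConfig(batch_size=64, max_epochs=40, patience=40,
                            learning_rate=2e-3, seed=3)
    return pv.fit(data, spec, config)
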