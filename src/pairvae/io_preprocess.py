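"""Readers and normalization recipes for paired cell-by-feature matrices.

Supported on-disk layouts:

* Matrix Market triplet: a directory with ``matrix.mtx``, ``features.tsv``
  and ``barcodes.tsv`` (orientation auto-detected by matching the barcode
  count against the matrix axes).
* Delimited text: header row of feature ids, first column of cell ids.
* 10x-style HDF5 feature-barcode container: one file holding both
  modalities, partitioned by ``feature_type``.

Normalization follows the classic recipe chain
filter -> (counts-per-million) -> log1p -> zero-mean/unit-variance scaling,
with named presets for the per-protocol variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "PairedDataset",
    "read_paired",
    "filter_features",
    "normalize_cpm",
    "log1p_transform",
    "scale_unit",
    "apply_preset",
    "select_top_variance",
    "PRESETS",
]


@dataclass
class PairedDataset:
    """Two aligned cell-by-feature matrices plus identifiers.

    Rows of ``X`` (n x p, modality 1) and ``Y`` (n x q, modality 2) refer
    to the same cells in the same order. ``labels`` are optional ground
    truth annotations used only for evaluation.
    """

    X: np.ndarray | sp.spmatrix
    Y: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    feature_ids_x: np.ndarray
    feature_ids_y: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids_x = np.asarray(self.feature_ids_x, dtype=object)
        self.feature_ids_y = np.asarray(self.feature_ids_y, dtype=object)
        n, p = self.X.shape
        ny, q = self.Y.shape
        if n != ny:
            raise ValueError(f"modalities disagree on cell count: {n} vs {ny}")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrices")
        if len(self.feature_ids_x) != p or len(self.feature_ids_y) != q:
            raise ValueError("feature id lengths do not match matrices")
        for name, ids in (("cell_ids", self.cell_ids),
                          ("feature_ids_x", self.feature_ids_x),
                          ("feature_ids_y", self.feature_ids_y)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate identifiers in {name}")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def shapes(self) -> tuple[int, int, int]:
        return self.X.shape[0], self.X.shape[1], self.Y.shape[1]


# ---------------------------------------------------------------------------
# readers

def _read_mtx_dir(path: Path) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Read a matrix.mtx/features.tsv/barcodes.tsv triplet as cells x features."""
    mtx_path = path / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    mat = sp.csr_matrix(mmread(mtx_path))
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].to_numpy(dtype=object)
    features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].to_numpy(dtype=object)
    if mat.shape[0] == len(barcodes):
        pass  # already cells x features
    elif mat.shape[1] == len(barcodes):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(barcodes)} barcodes on rows nor columns"
        )
    if mat.shape[1] != len(features):
        raise ValueError(f"feature axis {mat.shape[1]} != {len(features)} feature ids")
    return mat, barcodes, features


def _read_csv(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return (df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object).astype(object),
            df.columns.to_numpy(dtype=object))


def _read_h5_10x(path: Path) -> dict[str, tuple[sp.csr_matrix, np.ndarray, np.ndarray]]:
    """Read a 10x-style HDF5 container, returning one block per feature type."""
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["matrix"]
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
        shape = tuple(grp["shape"][:])  # (features, cells) as 10x writes it
        barcodes = np.array([b.decode() for b in grp["barcodes"][:]], dtype=object)
        feat_ids = np.array([b.decode() for b in grp["features"]["id"][:]], dtype=object)
        feat_types = np.array([b.decode() for b in grp["features"]["feature_type"][:]], dtype=object)
    mat = sp.csc_matrix((data, indices, indptr), shape=shape)  # features x cells, CSC
    cells_by_feat = sp.csr_matrix(mat.T)
    out = {}
    for ftype in pd.unique(feat_types):
        mask = feat_types == ftype
        out[ftype] = (sp.csr_matrix(cells_by_feat[:, mask]), barcodes, feat_ids[mask])
    return out


def read_paired(path_x, path_y, format: str, labels: np.ndarray | None = None) -> PairedDataset:
    """Read two modality sources and align their cells by barcode.

    Row order is taken from modality X; cells absent from either modality
    are dropped (count logged). For ``h5-10x``, both paths may point to
    the same container, whose feature types are split into the gene
    expression block (modality X) and the remaining block (modality Y).
    """
    path_x, path_y = Path(path_x), Path(path_y)
    for p in (path_x, path_y):
        if not p.exists():
            raise FileNotFoundError(f"cannot read modality source: {p}")
    if format == "mtx":
        X, bc_x, fx = _read_mtx_dir(path_x)
        Y, bc_y, fy = _read_mtx_dir(path_y)
    elif format == "csv":
        X, bc_x, fx = _read_csv(path_x)
        Y, bc_y, fy = _read_csv(path_y)
    elif format == "h5-10x":
        blocks = _read_h5_10x(path_x)
        gex_keys = [k for k in blocks if k.lower().replace(" ", "") == "geneexpression"]
        other_keys = [k for k in blocks if k not in gex_keys]
        if path_x == path_y:
            if not gex_keys or not other_keys:
                raise ValueError(
                    f"need a 'Gene Expression' block plus one other feature type; found {list(blocks)}"
                )
            X, bc_x, fx = blocks[gex_keys[0]]
            Y, bc_y, fy = blocks[other_keys[0]]
        else:
            blocks_y = _read_h5_10x(path_y)
            X, bc_x, fx = next(iter(blocks.values()))
            Y, bc_y, fy = next(iter(blocks_y.values()))
    else:
        raise ValueError(f"unknown format {format!r}; expected mtx, csv or h5-10x")

    for name, bc in (("X", bc_x), ("Y", bc_y)):
        if len(set(bc)) != len(bc):
            raise ValueError(f"duplicate barcodes in modality {name}")
    pos_y = {b: i for i, b in enumerate(bc_y)}
    keep = [i for i, b in enumerate(bc_x) if b in pos_y]
    if not keep:
        raise ValueError("no overlapping cell barcodes between modalities")
    dropped = (len(bc_x) - len(keep)) + (len(bc_y) - len(keep))
    if dropped:
        logger.warning("dropped %d cells absent from one modality", dropped)
    order_y = [pos_y[bc_x[i]] for i in keep]
    X = X[keep]
    Y = Y[order_y]
    data = PairedDataset(X=X, Y=Y, cell_ids=bc_x[keep],
                         feature_ids_x=fx, feature_ids_y=fy, labels=labels)
    n, p, q = data.shapes
    logger.info("read paired data: n=%d cells, p=%d, q=%d features", n, p, q)
    return data


# ---------------------------------------------------------------------------
# normalization primitives

def _nonzero_per_column(M) -> np.ndarray:
    if sp.issparse(M):
        return np.asarray((M != 0).sum(axis=0)).ravel()
    return np.count_nonzero(np.asarray(M), axis=0)


def filter_features(data: PairedDataset, modality: str, min_cells: int) -> PairedDataset:
    """Drop features detected in fewer than ``min_cells`` cells (inclusive keep)."""
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    if modality not in ("x", "y"):
        raise ValueError(f"modality must be 'x' or 'y', got {modality!r}")
    M = data.X if modality == "x" else data.Y
    ids = data.feature_ids_x if modality == "x" else data.feature_ids_y
    keep = _nonzero_per_column(M) >= min_cells
    if not keep.any():
        raise ValueError(
            f"min_cells={min_cells} removes every feature of modality {modality}; lower the threshold"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_features: dropped %d/%d features (modality %s)", n_dropped, keep.size, modality)
    sub = M[:, keep]
    if modality == "x":
        return replace(data, X=sub, feature_ids_x=ids[keep])
    return replace(data, Y=sub, feature_ids_y=ids[keep])


def normalize_cpm(M, cell_ids=None):
    """Rescale each row to sum to one million."""
    dense = not sp.issparse(M)
    arr = np.asarray(M, dtype=float) if dense else M.astype(float)
    if dense and (arr < 0).any():
        raise ValueError("counts-per-million requires nonnegative entries")
    if not dense and (arr.data < 0).any():
        raise ValueError("counts-per-million requires nonnegative entries")
    totals = np.asarray(arr.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        offenders = (np.asarray(cell_ids, dtype=object)[zero].tolist()
                     if cell_ids is not None else np.flatnonzero(zero).tolist())
        raise ValueError(f"zero-total rows cannot be normalized: {offenders}")
    scale = 1e6 / totals
    if dense:
        return arr * scale[:, None]
    return sp.csr_matrix(sp.diags(scale) @ arr)


def log1p_transform(M):
    """Elementwise natural log of (value + 1); counts/CPM input only."""
    if sp.issparse(M):
        if (M.data < 0).any():
            raise ValueError("log1p transform requires nonnegative entries")
        out = M.astype(float).copy()
        out.data = np.log1p(out.data)
        return out
    arr = np.asarray(M, dtype=float)
    if (arr < 0).any():
        raise ValueError("log1p transform requires nonnegative entries")
    return np.log1p(arr)


def scale_unit(M) -> np.ndarray:
    """Center each column to mean 0 and scale to unit sample variance (ddof=1).

    Constant columns map to all zeros. Output is always dense because
    centering destroys sparsity.
    """
    arr = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("scaling needs at least 2 rows to estimate variance")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    centered = arr - mean
    nonconst = sd > 0
    centered[:, nonconst] /= sd[nonconst]
    centered[:, ~nonconst] = 0.0
    return centered


def select_top_variance(data: PairedDataset, modality: str, k: int) -> PairedDataset:
    """Keep the k highest-variance features of one modality (optional helper)."""
    M = data.X if modality == "x" else data.Y
    arr = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    if k >= arr.shape[1]:
        return data
    var = arr.var(axis=0)
    keep = np.sort(np.argsort(var)[::-1][:k])
    if modality == "x":
        return replace(data, X=M[:, keep], feature_ids_x=data.feature_ids_x[keep])
    return replace(data, Y=M[:, keep], feature_ids_y=data.feature_ids_y[keep])


# ---------------------------------------------------------------------------
# per-protocol recipes

def _recipe(data: PairedDataset, *, filter_x=None, filter_y=None,
            cpm_x=False, cpm_y=False) -> PairedDataset:
    if filter_x is not None:
        data = filter_features(data, "x", filter_x)
    if filter_y is not None:
        data = filter_features(data, "y", filter_y)
    X, Y = data.X, data.Y
    if cpm_x:
        X = normalize_cpm(X, data.cell_ids)
    if cpm_y:
        Y = normalize_cpm(Y, data.cell_ids)
    X = scale_unit(log1p_transform(X))
    Y = scale_unit(log1p_transform(Y))
    return replace(data, X=X, Y=Y)


PRESETS = {
    # RNA + chromatin peaks: light filtering on both modalities, no CPM
    "multiome": lambda d: _recipe(d, filter_x=1, filter_y=1),
    # RNA + small antibody panel: filter RNA only
    "immune": lambda d: _recipe(d, filter_x=1),
    # RNA + ADT counts: stricter RNA filter and depth normalization
    "citeseq": lambda d: _recipe(d, filter_x=10, cpm_x=True, cpm_y=True),
    "none": lambda d: d,
}


def apply_preset(data: PairedDataset, name: str) -> PairedDataset:
    """Run one of the named normalization recipes on both modalities."""
    try:
        fn = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return fn(data)
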