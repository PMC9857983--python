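# pairvae

Joint embedding of paired two-modality single-cell data (RNA + ADT
antibodies, or RNA + ATAC peaks) through a shared-latent variational
model. A single low-dimensional latent vector per cell generates both
observed modalities via modality-specific nonlinear decoders; an
encoder reading only the gene-expression modality infers an approximate
Gaussian posterior. Training minimizes a KL regularizer toward the
standard-normal prior plus a `lambda`-weighted Gaussian reconstruction
error for both modalities, estimated with single-draw reparameterized
sampling and mini-batch adaptive-moment SGD.

The networks are implemented directly in NumPy (hand-written forward and
backward passes), so the package has no deep-learning framework
dependency and is fully deterministic under a single integer seed.

## Layout

| module | contents |
| --- | --- |
| `pairvae.io_preprocess` | readers (MTX triplet, CSV, 10x-style HDF5), feature filtering, CPM, log1p, unit-variance scaling, named per-protocol presets |
| `pairvae.model_core` | model spec, encoder/decoders, KL and reconstruction terms, weighted-ELBO objective, checkpointing |
| `pairvae.training` | mini-batch fitting with early stopping, embedding (`transform`), model persistence |
| `pairvae.latent_analysis` | Leiden clustering on a kNN graph, adjusted Rand index, Kendall tau-b, pseudo-bulk Pearson correlation |
| `pairvae.synthetic_data` | paired-data simulator with known latent clusters or a 1-D trajectory; fixture writer |

## CLI

```sh
# simulate a paired dataset with known ground truth
pairvae simulate --config sim.json --out data/ --format csv

# fit: writes a checkpoint directory (model_spec.json, weights.npz, history.csv)
pairvae fit --x data/x.csv --y data/y.csv --format csv --preset none \
    --latent-dim 10 --lambda 1.0 --epochs 100 --batch-size 128 --seed 0 \
    --out model/

# embed cells (posterior means, cells x d CSV)
pairvae transform --model model/ --x data/x.csv --out embedding.csv

# cluster the embedding and score against reference labels
pairvae evaluate --embedding embedding.csv --labels data/labels.csv \
    --out report.json
```

Normalization presets: `multiome` (filter min_cells=1 both modalities,
log1p, scale), `immune` (filter RNA only, log1p, scale), `citeseq`
(RNA: filter min_cells=10, CPM, log1p, scale; ADT: CPM, log1p, scale),
`none`.

Defaults chosen here and exposed as flags: latent dimensionality 10,
`lambda` 1.0, Adam at 1e-3, early stopping with patience 10 on a 10%
validation split.

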