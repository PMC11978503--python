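"""Readers and writers for count data and posterior bundles.

Counts load from H5AD files carrying "spliced"/"unspliced" layers (the
convention of velocity quantification pipelines) or from paired MTX +
feature/barcode TSV triplets, one per modality.  Matrices are oriented
cells x genes with 0-based indexing; cell and gene identifiers are preserved
through every stage.  Posterior bundles serialize to HDF5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inference import PosteriorBundle
from .measurement import CountData

__all__ = ["DatasetHandle", "load_counts", "save_counts", "save_bundle", "load_bundle"]


@dataclass
class DatasetHandle:
    """Where a dataset lives and which layers/keys to read."""

    path: str
    spliced_layer: str = "spliced"
    unspliced_layer: str = "unspliced"
    cluster_key: Optional[str] = None
    batch_key: Optional[str] = None
    embedding_key: Optional[str] = None


def _dense_int(x, name: str, round_policy: str = "warn"):
    if hasattr(x, "toarray"):
        x = x.toarray()
    x = np.asarray(x)
    if not np.allclose(x, np.round(x)):
        if round_policy == "error":
            raise ValueError(f"layer {name!r} contains non-integer values")
        import warnings

        warnings.warn(f"layer {name!r} contains non-integer values; rounding")
    return np.asarray(np.round(x), dtype=np.int64)


def load_counts(path, handle: Optional[DatasetHandle] = None, round_policy="warn") -> CountData:
    """Load a :class:`CountData` from H5AD or an MTX directory.

    For H5AD, spliced/unspliced layers are looked up by the handle's layer
    names; a missing layer raises an error naming the available layers.  For
    a directory, expects ``spliced.mtx``/``unspliced.mtx`` plus
    ``barcodes.tsv`` and ``features.tsv``.
    """
    path = Path(path)
    handle = handle or DatasetHandle(str(path))
    if path.is_dir():
        return _load_mtx_dir(path, round_policy)
    import anndata as ad

    adata = ad.read_h5ad(path)
    layers = dict(adata.layers)
    for layer in (handle.unspliced_layer, handle.spliced_layer):
        if layer not in layers:
            raise ValueError(
                f"layer {layer!r} not found; available layers: {sorted(layers)}"
            )
    clusters = batch = embedding = None
    if handle.cluster_key:
        clusters = pd.Series(np.asarray(adata.obs[handle.cluster_key]))
    elif "clusters" in adata.obs:
        clusters = pd.Series(np.asarray(adata.obs["clusters"]))
    if handle.batch_key:
        batch = pd.Series(np.asarray(adata.obs[handle.batch_key]))
    elif "batch" in adata.obs:
        batch = pd.Series(np.asarray(adata.obs["batch"]))
    emb_key = handle.embedding_key or next(
        (k for k in ("X_umap", "X_embedding", "X_pca") if k in adata.obsm), None
    )
    if emb_key is not None:
        embedding = np.asarray(adata.obsm[emb_key], dtype=float)
    return CountData(
        unspliced=_dense_int(layers[handle.unspliced_layer], handle.unspliced_layer, round_policy),
        spliced=_dense_int(layers[handle.spliced_layer], handle.spliced_layer, round_policy),
        gene_names=pd.Index(adata.var_names),
        cell_names=pd.Index(adata.obs_names),
        clusters=clusters,
        batch=batch,
        embedding=embedding,
    )


def _load_mtx_dir(path: Path, round_policy) -> CountData:
    from scipy.io import mmread

    mats = {}
    for name in ("spliced", "unspliced"):
        f = path / f"{name}.mtx"
        if not f.exists():
            raise ValueError(f"missing {f.name} in {path}")
        mats[name] = _dense_int(mmread(f).tocsr(), name, round_policy)
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0]
    features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0]
    return CountData(
        unspliced=mats["unspliced"],
        spliced=mats["spliced"],
        gene_names=pd.Index(features),
        cell_names=pd.Index(barcodes),
    )


def save_counts(data: CountData, path, truth_sidecar: Optional[dict] = None) -> None:
    """Write counts (plus metadata) to H5AD with spliced/unspliced layers."""
    import anndata as ad
    from scipy import sparse

    obs = pd.DataFrame(index=pd.Index(np.asarray(data.cell_names).astype(str)))
    if data.clusters is not None:
        obs["clusters"] = np.asarray(data.clusters)
    if data.batch is not None:
        obs["batch"] = np.asarray(data.batch)
    adata = ad.AnnData(
        X=sparse.csr_matrix(data.spliced.astype(np.float32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(np.asarray(data.gene_names).astype(str))),
        layers={
            "spliced": sparse.csr_matrix(data.spliced.astype(np.float32)),
            "unspliced": sparse.csr_matrix(data.unspliced.astype(np.float32)),
        },
    )
    if data.embedding is not None:
        adata.obsm["X_embedding"] = np.asarray(data.embedding)
    if truth_sidecar:
        adata.uns["ground_truth"] = {
            k: np.asarray(v) for k, v in truth_sidecar.items()
        }
    adata.write_h5ad(path)


def save_bundle(bundle: PosteriorBundle, path) -> None:
    """Serialize a posterior bundle (samples, ELBO trace, metadata) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("samples")
        for k, v in bundle.samples.items():
            g.create_dataset(k, data=v)
        f.create_dataset("elbo_trace", data=bundle.elbo_trace)
        f.attrs["seed"] = bundle.seed
        f.attrs["n_modules"] = bundle.n_modules
        f.attrs["t_max"] = bundle.t_max
        f.attrs["time_orientation"] = bundle.time_orientation
        f.attrs["extras"] = json.dumps(bundle.extras, default=float)
        f.create_dataset(
            "gene_names", data=np.asarray(bundle.gene_names).astype("S")
        )
        f.create_dataset(
            "cell_names", data=np.asarray(bundle.cell_names).astype("S")
        )


def load_bundle(path) -> PosteriorBundle:
    import h5py

    with h5py.File(path, "r") as f:
        samples = {k: np.asarray(v) for k, v in f["samples"].items()}
        return PosteriorBundle(
            samples=samples,
            elbo_trace=np.asarray(f["elbo_trace"]),
            seed=int(f.attrs["seed"]),
            n_modules=int(f.attrs["n_modules"]),
            t_max=float(f.attrs["t_max"]),
            gene_names=pd.Index([b.decode() for b in f["gene_names"][:]]),
            cell_names=pd.Index([b.decode() for b in f["cell_names"][:]]),
            time_orientation=int(f.attrs["time_orientation"]),
            extras=json.loads(f.attrs["extras"]),
        )
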