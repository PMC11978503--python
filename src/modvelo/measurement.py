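"""Measurement model: from biological expectations to observed raw counts.

Biological expectations ``x^B`` (expected unspliced/spliced counts from the
kinetics layer) are distorted by technical effects before sequencing.  The
measurement expectation for cell ``c``, gene ``g`` and modality
``j in {unspliced, spliced}`` is

    x^M_cgj = l_cgj * (soup_{e(c), g, j} + x^B_cgj)

where ``l_cgj`` is a multiplicative detection efficiency, ``soup`` is the
ambient ("cell-free") RNA level of the cell's experimental batch ``e(c)``,
and batch membership is a one-hot design matrix.  Detection is factorized as
(per-cell) x (per-modality) x (optional per-gene-and-modality) rather than a
free cell x gene matrix, which would be unidentifiable.

Observed raw counts follow a negative binomial with mean ``x^M`` and
gene-by-modality concentration ``a_gj`` under the Gamma-Poisson
(mean-concentration) convention:

    X ~ NB(mu, a)   with   Var[X] = mu + mu^2 / a,

so large ``a`` approaches a Poisson model.  Note the scale non-identifiability
of the expectation: doubling ``l`` while halving ``soup + x^B`` leaves ``x^M``
(and hence the likelihood) unchanged; the priors of the inference layer are
what break this degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .kinetics import BiologicalExpectation, GeneRates, ModuleKinetics, expected_counts

__all__ = [
    "MeasurementParameters",
    "BatchDesign",
    "CountData",
    "measurement_expectation",
    "nb_loglik",
    "model_loglik",
]

MODALITIES = ("unspliced", "spliced")


@dataclass
class BatchDesign:
    """One-hot assignment of cells to experimental batches (rows sum to 1)."""

    one_hot: np.ndarray

    def __post_init__(self) -> None:
        self.one_hot = np.atleast_2d(np.asarray(self.one_hot, dtype=float))
        row_sums = self.one_hot.sum(axis=1)
        if self.one_hot.size and not np.all(row_sums == 1.0):
            raise ValueError("every cell must belong to exactly one batch")
        if np.any((self.one_hot != 0.0) & (self.one_hot != 1.0)):
            raise ValueError("batch design must be one-hot")

    @classmethod
    def from_labels(cls, labels: Sequence) -> "BatchDesign":
        labels = pd.Categorical(labels)
        return cls(np.eye(len(labels.categories))[labels.codes])

    @property
    def n_batches(self) -> int:
        return self.one_hot.shape[1]

    @property
    def batch_index(self) -> np.ndarray:
        return self.one_hot.argmax(axis=1)


@dataclass
class MeasurementParameters:
    """Detection efficiencies, ambient levels and NB concentrations.

    detection_cell : (C,) per-cell efficiency (e.g. sequencing depth)
    detection_modality : (2,) unspliced/spliced efficiency
    detection_gene : optional (G, 2) per-gene-and-modality efficiency
    ambient : (E, G, 2) ambient RNA ("soup") per batch; zero for clean data
    overdispersion : (G, 2) NB concentration a_gj
    """

    detection_cell: np.ndarray
    detection_modality: np.ndarray
    ambient: np.ndarray
    overdispersion: np.ndarray
    detection_gene: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.detection_cell = np.atleast_1d(np.asarray(self.detection_cell, float))
        self.detection_modality = np.asarray(self.detection_modality, float)
        self.ambient = np.asarray(self.ambient, float)
        self.overdispersion = np.asarray(self.overdispersion, float)
        if self.detection_gene is not None:
            self.detection_gene = np.asarray(self.detection_gene, float)
            if np.any(self.detection_gene <= 0):
                raise ValueError("detection efficiencies must be > 0")
        if np.any(self.detection_cell <= 0) or np.any(self.detection_modality <= 0):
            raise ValueError("detection efficiencies must be > 0")
        if np.any(self.ambient < 0):
            raise ValueError("ambient levels must be >= 0")
        if np.any(self.overdispersion <= 0):
            raise ValueError("overdispersion concentrations must be > 0")

    def detection(self) -> np.ndarray:
        """Full detection tensor ``l_cgj`` with shape (C, 1 or G, 2)."""
        l = self.detection_cell[:, None, None] * self.detection_modality
        if self.detection_gene is not None:
            l = l * self.detection_gene
        return l


@dataclass
class CountData:
    """Observed raw spliced/unspliced UMI counts with cell metadata."""

    unspliced: np.ndarray
    spliced: np.ndarray
    gene_names: pd.Index = None
    cell_names: pd.Index = None
    clusters: Optional[pd.Series] = None
    batch: Optional[pd.Series] = None
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("unspliced", "spliced"):
            x = getattr(self, name)
            if hasattr(x, "toarray"):
                x = x.toarray()
            x = np.asarray(x)
            if np.any(x < 0):
                raise ValueError(f"{name} counts must be >= 0")
            if not np.allclose(x, np.round(x)):
                raise ValueError(f"{name} counts must be integers")
            setattr(self, name, np.asarray(np.round(x), dtype=np.int64))
        if self.unspliced.shape != self.spliced.shape:
            raise ValueError("spliced and unspliced layers must share cell/gene axes")
        c, g = self.spliced.shape
        if self.gene_names is None:
            self.gene_names = pd.Index([f"gene_{i}" for i in range(g)])
        if self.cell_names is None:
            self.cell_names = pd.Index([f"cell_{i}" for i in range(c)])
        self.gene_names = pd.Index(self.gene_names)
        self.cell_names = pd.Index(self.cell_names)
        if len(self.gene_names) != g or len(self.cell_names) != c:
            raise ValueError("metadata does not match count matrix shape")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def stacked(self) -> np.ndarray:
        """Counts as a (C, G, 2) tensor ordered (unspliced, spliced)."""
        return np.stack([self.unspliced, self.spliced], axis=-1)

    def batch_design(self) -> BatchDesign:
        if self.batch is None:
            return BatchDesign(np.ones((self.n_cells, 1)))
        return BatchDesign.from_labels(np.asarray(self.batch))

    def subset_genes(self, mask_or_index) -> "CountData":
        idx = np.asarray(mask_or_index)
        return CountData(
            unspliced=self.unspliced[:, idx],
            spliced=self.spliced[:, idx],
            gene_names=self.gene_names[idx],
            cell_names=self.cell_names,
            clusters=self.clusters,
            batch=self.batch,
            embedding=self.embedding,
        )


def _as_stacked_expectation(x) -> np.ndarray:
    if isinstance(x, BiologicalExpectation):
        return np.stack([x.unspliced, x.spliced], axis=-1)
    return np.asarray(x, dtype=float)


def measurement_expectation(
    biological, params: MeasurementParameters, design: BatchDesign
) -> np.ndarray:
    """Expected observed counts ``x^M = l * (soup-of-own-batch + x^B)``.

    ``biological`` is a :class:`BiologicalExpectation` or a (C, G, 2) array;
    returns a (C, G, 2) array.
    """
    xb = _as_stacked_expectation(biological)
    if design.one_hot.shape[0] != xb.shape[0]:
        raise ValueError("batch design does not cover every cell")
    soup = params.ambient[design.batch_index]  # (C, G, 2)
    return params.detection() * (soup + xb)


def nb_loglik(counts, mean, concentration) -> np.ndarray:
    """Elementwise log-pmf of NB(mu, a) with Var = mu + mu^2/a.

    ``counts`` must be nonnegative integers; broadcasting applies.
    """
    x = np.asarray(counts)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be nonnegative integers")
    x = np.asarray(np.round(x), dtype=float)
    mu = np.asarray(mean, dtype=float)
    a = np.asarray(concentration, dtype=float)
    if np.any(mu <= 0) or np.any(a <= 0):
        raise ValueError("mean and concentration must be > 0")
    return (
        gammaln(x + a)
        - gammaln(a)
        - gammaln(x + 1.0)
        + a * np.log(a / (a + mu))
        + x * np.log(mu / (a + mu))
    )


def model_loglik(
    data: CountData,
    kinetics: ModuleKinetics,
    rates: GeneRates,
    times: np.ndarray,
    params: MeasurementParameters,
    design: Optional[BatchDesign] = None,
) -> float:
    """Total NB log-likelihood of the data under a full parameter set.

    Composes the kinetic closed forms, the measurement transformation and the
    NB observation model, summing over cells, genes and modalities.
    """
    if data.n_genes == 0:
        return 0.0
    if design is None:
        design = data.batch_design()
    xb = expected_counts(np.asarray(times, float), kinetics, rates)
    xm = measurement_expectation(xb, params, design)
    ll = nb_loglik(data.stacked(), np.maximum(xm, 1e-12), params.overdispersion)
    return float(ll.sum())
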