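"""Trajectory-direction benchmarking: cross-boundary directional correctness.

CBDir scores whether an embedded velocity field points from a source cluster
toward a target cluster across their shared boundary.  For a boundary cell
``c`` of the source cluster (a cell with at least one kNN neighbor in the
target cluster),

    CBDir(c) = (1 / |N(c) ∩ C_target|) * sum_{c' in N(c) ∩ C_target}
               cos( v_c , x_c' - x_c )

with low-dimensional positions ``x`` and velocities ``v``.  A transition's
score is the mean over its boundary cells; values lie in [-1, 1] and are
positive iff the flow crosses the boundary in the stated direction.  Terms
with a zero-norm velocity or displacement are undefined; they are excluded
from both the sum and the normalizer, which keeps scores bounded.

Also provided: a time-concordance metric — the sign agreement of posterior
cluster-time differences with ground-truth transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionSpec",
    "EmbeddedVelocityField",
    "knn_indices",
    "boundary_cells",
    "cbdir",
    "time_concordance",
]


@dataclass
class TransitionSpec:
    """Ordered ground-truth (source, target) cluster transitions."""

    transitions: list

    def __post_init__(self) -> None:
        self.transitions = [tuple(t) for t in self.transitions]
        if not all(len(t) == 2 for t in self.transitions):
            raise ValueError("each transition must be a (source, target) pair")

    @classmethod
    def from_chain(cls, chain: Sequence) -> "TransitionSpec":
        """A linear lineage a -> b -> c becomes [(a, b), (b, c)]."""
        return cls(list(zip(chain[:-1], chain[1:])))

    def validate(self, clusters) -> None:
        known = set(np.asarray(clusters))
        for s, t in self.transitions:
            if s not in known or t not in known:
                raise ValueError(f"unknown cluster in transition ({s}, {t})")


@dataclass
class EmbeddedVelocityField:
    """Low-dimensional positions and velocities plus a kNN structure."""

    positions: np.ndarray  # (C, d)
    velocities: np.ndarray  # (C, d)
    neighbors: np.ndarray  # (C, k) integer indices

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.neighbors = np.atleast_2d(np.asarray(self.neighbors, dtype=int))
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share dimensionality")
        if self.neighbors.shape[0] != self.positions.shape[0]:
            raise ValueError("neighbor table must cover every cell")


def knn_indices(positions, n_neighbors: int = 30) -> np.ndarray:
    """(C, k) nearest-neighbor indices in the embedding (excluding self)."""
    from sklearn.neighbors import NearestNeighbors

    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    k = int(min(n_neighbors, positions.shape[0] - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(positions)
    _, idx = nn.kneighbors(positions)
    return idx[:, 1:]


def boundary_cells(clusters, neighbors, source, target):
    """Cells of ``source`` adjacent to ``target`` (and the symmetric set).

    Returns ``(source_boundary, target_boundary)`` as integer index arrays.
    """
    labels = np.asarray(clusters)
    for name in (source, target):
        if name not in set(labels):
            raise ValueError(f"unknown cluster {name!r}")
    neighbors = np.asarray(neighbors)
    neigh_labels = labels[neighbors]  # (C, k)
    src_cells = np.flatnonzero(labels == source)
    tgt_cells = np.flatnonzero(labels == target)
    src_boundary = src_cells[(neigh_labels[src_cells] == target).any(axis=1)]
    tgt_boundary = tgt_cells[(neigh_labels[tgt_cells] == source).any(axis=1)]
    return src_boundary, tgt_boundary


def _cbdir_cell(field: EmbeddedVelocityField, cell: int, target_mask: np.ndarray):
    """Mean cosine between v_cell and displacements to target neighbors."""
    neigh = field.neighbors[cell]
    neigh = neigh[target_mask[neigh]]
    if neigh.size == 0:
        return np.nan
    v = field.velocities[cell]
    v_norm = np.linalg.norm(v)
    total, norm = 0.0, 0
    for j in neigh:
        d = field.positions[j] - field.positions[cell]
        d_norm = np.linalg.norm(d)
        if v_norm == 0.0 or d_norm == 0.0:
            continue  # undefined cosine: drop term and shrink the normalizer
        total += float(v @ d) / (v_norm * d_norm)
        norm += 1
    return total / norm if norm else np.nan


def cbdir(
    field: EmbeddedVelocityField, clusters, spec: TransitionSpec
) -> pd.DataFrame:
    """Per-transition CBDir scores plus their unweighted mean.

    Transitions with an empty boundary (or only undefined terms) are
    reported as NaN and excluded from the mean.  The returned frame has one
    row per transition and a final "mean" row.
    """
    labels = np.asarray(clusters)
    spec.validate(labels)
    rows = []
    for source, target in spec.transitions:
        src_boundary, _ = boundary_cells(labels, field.neighbors, source, target)
        target_mask = labels == target
        scores = [_cbdir_cell(field, c, target_mask) for c in src_boundary]
        scores = [s for s in scores if np.isfinite(s)]
        rows.append(
            {
                "source": source,
                "target": target,
                "n_boundary": len(scores),
                "cbdir": float(np.mean(scores)) if scores else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    valid = df["cbdir"].dropna()
    df.loc[len(df)] = {
        "source": "mean",
        "target": "",
        "n_boundary": int(df["n_boundary"].sum()),
        "cbdir": float(valid.mean()) if len(valid) else np.nan,
    }
    return df


def time_concordance(cell_times, clusters, spec: TransitionSpec) -> pd.DataFrame:
    """Sign agreement of cluster mean times with ground-truth transitions.

    Each transition scores +1 if the target cluster's mean posterior time
    exceeds the source's, -1 if it is lower, and 0 (tie flag) if equal.
    The summary row reports the fraction of concordant transitions.
    """
    times = np.asarray(cell_times, dtype=float)
    labels = np.asarray(clusters)
    spec.validate(labels)
    rows = []
    for source, target in spec.transitions:
        dt = times[labels == target].mean() - times[labels == source].mean()
        rows.append(
            {
                "source": source,
                "target": target,
                "delta_time": float(dt),
                "concordant": int(np.sign(dt)),
            }
        )
    df = pd.DataFrame(rows)
    frac = float((df["concordant"] > 0).mean())
    df.loc[len(df)] = {
        "source": "fraction_concordant",
        "target": "",
        "delta_time": np.nan,
        "concordant": frac,
    }
    return df
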