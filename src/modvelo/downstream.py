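"""Module-level analytics and velocity-graph construction from a posterior.

All operations consume a fitted :class:`~modvelo.inference.PosteriorBundle`
and are posterior-aware: quantities are evaluated per joint posterior sample
and summarized, so uncertain parameters contribute less sharply.

* **Module activation** — the spliced counts a module has produced in a cell,
  obtained by substituting posterior parameter samples into the closed-form
  time evolution of spliced counts at the cell's posterior time.
* **Normalized activation** — activation divided by the module's steady-state
  counts (time set to infinity), mapping each module to a [0, 1] progress
  coordinate during induction.
* **Module state** — OFF if the cell time is below the module's switch-on
  time or normalized activation < 0.05; ON if normalized activation > 0.95;
  otherwise induction or repression depending on whether the cell time is
  below or above the switch-off time.
* **Velocity graph** — cell-to-cell transition probabilities from cosine
  similarity between a cell's velocity vector and expression displacements
  to its embedding neighbors, averaged over posterior velocity samples.
* **Module markers** — genes ranked by the fraction of their transcription
  rate explained by a module.
* **Steady-state reference** — per-module expression signatures
  ``g_mg = alpha_hat_mg / gamma_g`` for spatial deconvolution tools.
* **Transition confidence** — fraction of posterior time samples of a
  putative descendant cluster exceeding the 90th percentile of the putative
  ancestor cluster's samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorBundle
from .kinetics import module_spliced
from .measurement import CountData

__all__ = [
    "ModuleActivation",
    "SteadyStateReference",
    "module_activation",
    "normalized_activation",
    "module_state",
    "module_states",
    "velocity_graph",
    "velocity_samples",
    "module_markers",
    "steady_state_reference",
    "transition_confidence",
    "plot_activation",
]

STATE_LABELS = ("OFF", "induction", "ON", "repression")
OFF_THRESHOLD = 0.05
ON_THRESHOLD = 0.95


@dataclass
class ModuleActivation:
    """Posterior summary of per-cell module activation.

    ``activation``: (C, M) posterior-mean spliced counts produced by each
    module (summed over genes); ``per_gene``: (C, M, G) posterior mean;
    ``samples``: (S, C, M) per-sample totals; ``normalized``: (C, M)
    activation / steady-state counts; ``undefined``: (M,) flags for modules
    with zero steady state.
    """

    activation: np.ndarray
    per_gene: np.ndarray
    samples: np.ndarray
    normalized: np.ndarray
    undefined: np.ndarray


def _activation_samples(bundle: PosteriorBundle, per_gene: bool = False):
    """Per-sample spliced-count components at the posterior cell times."""
    S = bundle.n_samples
    totals = []
    gene_acc = None
    ss_tot = []
    for i in range(S):
        kin, rates, times = bundle.kinetics_sample(i)
        s_comp = module_spliced(times, kin, rates)  # (C, M, G)
        totals.append(s_comp.sum(axis=-1))
        if per_gene:
            gene_acc = s_comp if gene_acc is None else gene_acc + s_comp
        ss_tot.append((kin.target_rate / rates.degradation).sum(axis=-1))  # (M,)
    samples = np.stack(totals)  # (S, C, M)
    ss = np.stack(ss_tot)  # (S, M)
    per_gene_mean = gene_acc / S if per_gene else None
    return samples, ss, per_gene_mean


def module_activation(bundle: PosteriorBundle) -> ModuleActivation:
    """Spliced counts produced by each module in each cell.

    Evaluates the closed-form spliced-count components at posterior parameter
    samples; both the posterior mean and the samples are exposed.
    """
    samples, ss, per_gene = _activation_samples(bundle, per_gene=True)
    ss_mean = ss.mean(axis=0)
    undefined = ss_mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(
            undefined, np.nan, samples.mean(axis=0) / np.where(undefined, 1.0, ss_mean)
        )
    return ModuleActivation(
        activation=samples.mean(axis=0),
        per_gene=per_gene,
        samples=samples,
        normalized=normalized,
        undefined=undefined,
    )


def normalized_activation(bundle: PosteriorBundle) -> np.ndarray:
    """(C, M) fraction of steady-state counts each module has reached.

    NaN for modules whose steady state is zero (undefined)."""
    return module_activation(bundle).normalized


def module_state(norm_activation, t, t_on, t_off):
    """Classify one (cell, module) pair into OFF/induction/ON/repression.

    OFF if ``t < t_on`` or normalized activation < 0.05; ON if normalized
    activation > 0.95; otherwise induction (``t < t_off``) or repression
    (``t >= t_off``).  Vectorized over broadcastable inputs.
    """
    norm = np.asarray(norm_activation, dtype=float)
    t = np.asarray(t, dtype=float)
    off = (t < t_on) | (norm < OFF_THRESHOLD)
    on = ~off & (norm > ON_THRESHOLD)
    induction = ~off & ~on & (t < t_off)
    out = np.full(np.broadcast_shapes(norm.shape, t.shape), "repression", dtype=object)
    out[np.broadcast_to(induction, out.shape)] = "induction"
    out[np.broadcast_to(on, out.shape)] = "ON"
    out[np.broadcast_to(off, out.shape)] = "OFF"
    return out if out.ndim else out.item()


def module_states(bundle: PosteriorBundle) -> pd.DataFrame:
    """(cells x modules) state labels from posterior-mean quantities."""
    act = module_activation(bundle)
    t = bundle.posterior_mean("t")[:, None]
    t_on = bundle.posterior_mean("t_on")[None, :]
    t_off = bundle.posterior_mean("t_off")[None, :]
    labels = module_state(act.normalized, t, t_on, t_off)
    return pd.DataFrame(
        labels,
        index=bundle.cell_names,
        columns=[f"module_{m}" for m in range(bundle.n_modules)],
    )


# ---------------------------------------------------------------------------
# Velocity graph
# ---------------------------------------------------------------------------


def _log_smoothed_expression(data: CountData, n_pcs: int = 30, n_neighbors: int = 30):
    """Depth-normalized, log1p, kNN-smoothed spliced expression + kNN indices."""
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    s = data.spliced.astype(float)
    depth = s.sum(axis=1)
    depth = np.where(depth == 0, 1.0, depth)
    x = np.log1p(s / depth[:, None] * np.median(depth))
    n_comp = int(min(n_pcs, x.shape[0] - 1, x.shape[1] - 1))
    pcs = PCA(n_components=n_comp, random_state=0).fit_transform(x) if n_comp >= 2 else x
    k = int(min(n_neighbors, x.shape[0] - 1))
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    smoothed = x[idx].mean(axis=1)
    return smoothed, idx


def velocity_samples(bundle: PosteriorBundle, n_samples: Optional[int] = None):
    """Posterior velocity samples (n_samples, C, G) in spliced-count space."""
    from .kinetics import velocity as _velocity

    S = bundle.n_samples if n_samples is None else min(n_samples, bundle.n_samples)
    out = []
    for i in range(S):
        kin, rates, times = bundle.kinetics_sample(i)
        out.append(_velocity(times, kin, rates))
    return np.stack(out)


def velocity_graph(
    bundle: PosteriorBundle,
    data: CountData,
    n_samples: int = 100,
    n_neighbors: int = 30,
    n_pcs: int = 30,
    kernel_scale: float = 0.25,
    neighbor_indices: Optional[np.ndarray] = None,
):
    """Cell x cell transition-probability matrix averaged over the posterior.

    For every posterior velocity sample, the cosine similarity between a
    cell's velocity (transformed to log-expression space) and the
    displacement of log-smoothed expression toward each kNN neighbor is
    passed through an exponential kernel and row-normalized; the resulting
    transition matrices are averaged over ``n_samples`` samples, so genes
    with uncertain velocities carry less weight.  Returns
    ``(transitions, neighbor_indices, isolated)`` where ``transitions`` is a
    dense (C, k) matrix of probabilities aligned with ``neighbor_indices``.
    """
    smoothed, idx = _log_smoothed_expression(data, n_pcs=n_pcs, n_neighbors=n_neighbors)
    if neighbor_indices is not None:
        idx = np.asarray(neighbor_indices)
    C = data.n_cells
    vel = velocity_samples(bundle, n_samples)
    S = vel.shape[0]
    # velocity in log1p expression space, then displacement cosine
    disp = smoothed[idx] - smoothed[:, None, :]  # (C, k, G)
    disp_norm = np.linalg.norm(disp, axis=-1)
    acc = np.zeros((C, idx.shape[1]))
    spliced_mean = np.maximum(data.spliced.astype(float), 0.0) + 1.0
    for i in range(S):
        v = vel[i] / spliced_mean  # d log(1+s)/dt proxy
        v_norm = np.linalg.norm(v, axis=-1)
        dots = np.einsum("ckg,cg->ck", disp, v)
        denom = disp_norm * v_norm[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
        kern = np.exp(cos / kernel_scale)
        acc += kern / kern.sum(axis=1, keepdims=True)
    trans = acc / S
    isolated = np.zeros(C, dtype=bool)  # kNN always yields neighbors here
    return trans, idx, isolated


def embed_velocity(trans: np.ndarray, idx: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Project velocities into an embedding via transition expectations.

    ``v_c = sum_j T_cj * unit(x_j - x_c) - mean_j unit(x_j - x_c)``: the
    expected drift under the transition kernel minus the uniform baseline.
    """
    disp = embedding[idx] - embedding[:, None, :]
    norm = np.linalg.norm(disp, axis=-1, keepdims=True)
    unit = np.where(norm > 0, disp / np.where(norm > 0, norm, 1.0), 0.0)
    return np.einsum("ck,ckd->cd", trans, unit) - unit.mean(axis=1)


# ---------------------------------------------------------------------------
# Markers, steady-state reference, transition confidence
# ---------------------------------------------------------------------------


def module_markers(bundle: PosteriorBundle, module: int, k: int = 30) -> pd.DataFrame:
    """Top-k genes ranked by the transcription-rate fraction of a module.

    The score of gene g for module m is ``ahat_mg / sum_m' ahat_m'g``
    (posterior means); ties break by absolute target rate, then gene name.
    Genes with an all-zero total rate are excluded.
    """
    if not 0 <= module < bundle.n_modules:
        raise ValueError(f"unknown module {module}")
    ahat = bundle.posterior_mean("ahat")  # (M, G)
    total = ahat.sum(axis=0)
    ok = total > 0
    frac = np.where(ok, ahat[module] / np.where(ok, total, 1.0), np.nan)
    df = pd.DataFrame(
        {
            "gene": bundle.gene_names,
            "fraction": frac,
            "target_rate": ahat[module],
        }
    )[ok]
    df = df.sort_values(
        ["fraction", "target_rate", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(k)


@dataclass
class SteadyStateReference:
    """Steady-state spliced counts g_mg = ahat_mg / gamma_g per module."""

    table: pd.DataFrame  # genes x modules

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "SteadyStateReference":
        return cls(pd.read_csv(path, index_col=0))


def steady_state_reference(
    bundle: PosteriorBundle, detection_normalize: bool = False
) -> SteadyStateReference:
    """Per-module steady-state expression signatures (genes x modules).

    ``detection_normalize`` optionally multiplies by the posterior-mean
    spliced detection efficiency, mapping signatures to observed-count scale.
    """
    ahat = bundle.posterior_mean("ahat")  # (M, G)
    gamma = bundle.posterior_mean("gamma")
    g_mg = ahat / gamma  # (M, G)
    if detection_normalize:
        g_mg = g_mg * bundle.posterior_mean("l_mod")[1]
    table = pd.DataFrame(
        g_mg.T,
        index=pd.Index(bundle.gene_names, name="gene"),
        columns=[f"module_{m}" for m in range(bundle.n_modules)],
    )
    return SteadyStateReference(table)


def transition_confidence(ancestor_times, descendant_times, q: float = 0.90) -> float:
    """Confidence that ``descendant`` is downstream of ``ancestor``.

    Fraction of pooled posterior time samples of the descendant cluster that
    exceed the ``q`` quantile of the ancestor cluster's pooled samples.
    Under identical time distributions the expectation is ``1 - q``.
    """
    anc = np.asarray(ancestor_times, dtype=float).ravel()
    dec = np.asarray(descendant_times, dtype=float).ravel()
    if anc.size == 0 or dec.size == 0:
        raise ValueError("both clusters need at least one time sample")
    return float(np.mean(dec > np.quantile(anc, q)))


def cluster_transition_confidence(
    bundle: PosteriorBundle, clusters: Sequence, source, target, q: float = 0.90
) -> float:
    """Transition confidence between two cluster labels, pooling samples."""
    labels = np.asarray(clusters)
    t = bundle.samples["t"]  # (S, C)
    src = t[:, labels == source]
    tgt = t[:, labels == target]
    if src.size == 0 or tgt.size == 0:
        raise ValueError("empty cluster")
    return transition_confidence(src, tgt, q=q)


def plot_activation(bundle: PosteriorBundle, ax=None):
    """Convenience: posterior-mean module activation against posterior time."""
    import matplotlib.pyplot as plt

    act = module_activation(bundle)
    t = bundle.posterior_mean("t")
    if ax is None:
        _, ax = plt.subplots()
    order = np.argsort(t)
    for m in range(bundle.n_modules):
        ax.plot(t[order], act.activation[order, m], label=f"module {m}", lw=1)
    ax.set_xlabel("posterior time")
    ax.set_ylabel("module activation (spliced counts)")
    ax.legend()
    return ax
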