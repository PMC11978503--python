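"""Variational Bayesian inference for the modular velocity model.

The full generative model is

    alpha, u, s     closed-form module kinetics (kinetics layer)
    x^M             detection/ambient/batch transformation (measurement layer)
    X ~ NB(x^M, a)  gene-by-modality overdispersed counts

with latent parameters: per-cell time ``T_c`` and detection ``l_c``; per-gene
splicing ``beta_g``, degradation ``gamma_g`` and NB concentrations ``a_gj``;
per-module target rates ``alpha_hat_mg``, relaxation rates ``lam_m,ON/OFF``
and switch times ``T_m,ON < T_m,OFF``; per-modality detection ``l_j``; and,
for multi-batch data, ambient levels ``soup_egj``.  All positive parameters
carry lognormal priors on a hierarchical structure (gene-level rates share an
inferred hyper-mean, which shares evidence strength across genes); NB
concentrations carry a gamma prior; the cell-time prior has unit coefficient
of variation, so that on data without dynamics the posterior time CV relaxes
toward ~1.

Inference is stochastic variational inference: a mean-field Gaussian
variational family over log-transformed parameters, reparameterized sampling
(one Monte Carlo sample per step) and Adam.  Gradients of the expected
log-joint are exact-to-first-order and cheap, exploiting the separability of
the likelihood:

* gradients with respect to detection, ambient and overdispersion parameters
  are analytic (chain rule through the NB log-pmf);
* gradients with respect to kinetic parameters use forward finite differences
  of the biological expectations, batched into a single vectorized kinetics
  evaluation: perturbing *all* genes' ``beta`` (or all modules' ``lam``, ...)
  simultaneously is valid because each gene's likelihood depends only on its
  own gene-level parameters, and each module's *component* depends only on
  its own module-level parameters.

The orientation of latent time (trajectories fitted backwards are a classic
local optimum) is resolved by running two short pilot fits with opposite
time initializations and continuing the one with the better ELBO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, ndtri

from . import _fastkin
from .kinetics import GeneRates, ModuleKinetics
from .measurement import BatchDesign, CountData, MeasurementParameters

__all__ = [
    "PriorConfig",
    "PosteriorBundle",
    "fit",
    "filter_genes",
    "select_num_modules",
    "posterior_time_cv",
]

_FD_EPS = 1e-5  # forward-difference step in unconstrained (log) space
_MU_EPS = 1e-3  # jitter added to NB means: keeps gradients bounded at zero expectation


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Priors, variational-family and optimizer settings.

    Prior entries are (mean, sd) of a Normal on the log of the parameter
    unless noted.  ``t_max`` sets the trajectory timescale (arbitrary units);
    the cell-time prior has median ``t_max / 2`` and unit CV.
    """

    n_modules: Optional[int] = None  # None: choose via select_num_modules
    t_max: float = 10.0
    num_posterior_samples: int = 100

    # priors (log-space mean, sd)
    time_sigma: float = 0.8326  # lognormal sigma giving prior CV = 1.0
    rate_hyper: tuple = (np.log(0.45), 0.5)  # hyper-mean prior for beta and gamma
    rate_sigma: float = 0.9  # spans half-lives of ~20 min to ~7 h around the hyper-mean
    lam_prior: tuple = (np.log(1.5), 0.7)
    target_hyper: tuple = (np.log(0.5), 1.0)
    target_sigma: float = 1.5
    switch_on_sigma: float = 0.8
    switch_len_sigma: float = 0.8
    detection_cell_sigma: float = 0.25
    detection_modality_sigma: float = 0.5
    ambient_prior: tuple = (np.log(0.02), 1.5)
    overdispersion_gamma: tuple = (2.0, 0.2)  # shape, rate on the natural scale

    # variational family / optimizer
    time_init: str = "ranked"  # "ranked": spread along PC1; "flat": prior median
    epochs: int = 1000
    pilot_epochs: int = 150
    learning_rate: float = 0.05
    lr_decay: float = 0.1  # final lr = learning_rate * lr_decay
    average_frac: float = 0.4  # Polyak-average the last fraction of iterates
    infer_ambient: Optional[bool] = None  # default: only when >1 batch

    def __post_init__(self) -> None:
        if self.n_modules is not None and self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.num_posterior_samples < 1:
            raise ValueError("num_posterior_samples must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PriorConfig":
        """Load settings from a YAML mapping of PriorConfig field names."""
        import dataclasses

        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("rate_hyper", "lam_prior", "target_hyper", "ambient_prior",
                    "overdispersion_gamma"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class FitDivergence(RuntimeError):
    """Raised when the ELBO becomes non-finite during optimization."""


# ---------------------------------------------------------------------------
# Posterior bundle
# ---------------------------------------------------------------------------


@dataclass
class PosteriorBundle:
    """Joint posterior samples of every latent parameter plus fit metadata.

    ``samples[name]`` has leading dimension ``S`` (number of joint samples).
    Keys: t, l_cell, l_mod, beta, gamma, a, ahat, lam_on, lam_off, t_on,
    t_off and (multi-batch fits) soup.
    """

    samples: dict
    elbo_trace: np.ndarray
    seed: int
    n_modules: int
    t_max: float
    gene_names: pd.Index
    cell_names: pd.Index
    time_orientation: int = 1
    extras: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.samples[name].mean(axis=0)

    def kinetics_sample(self, i: int):
        """(ModuleKinetics, GeneRates, times) for joint sample ``i``."""
        s = self.samples
        kin = ModuleKinetics(
            target_rate=s["ahat"][i],
            activation_rate=s["lam_on"][i],
            deactivation_rate=s["lam_off"][i],
            switch_on=s["t_on"][i],
            switch_off=s["t_off"][i],
        )
        rates = GeneRates(splicing=s["beta"][i], degradation=s["gamma"][i])
        return kin, rates, s["t"][i]

    def kinetics_mean(self):
        """Posterior-mean kinetics (module order as fitted)."""
        kin = ModuleKinetics(
            target_rate=self.posterior_mean("ahat"),
            activation_rate=self.posterior_mean("lam_on"),
            deactivation_rate=self.posterior_mean("lam_off"),
            switch_on=self.posterior_mean("t_on"),
            switch_off=self.posterior_mean("t_off"),
        )
        rates = GeneRates(
            splicing=self.posterior_mean("beta"),
            degradation=self.posterior_mean("gamma"),
        )
        return kin, rates, self.posterior_mean("t")

    def measurement_sample(self, i: int) -> MeasurementParameters:
        s = self.samples
        c = s["t"].shape[1]
        ambient = s["soup"][i] if "soup" in s else np.zeros((1, s["beta"].shape[1], 2))
        return MeasurementParameters(
            detection_cell=s["l_cell"][i],
            detection_modality=s["l_mod"][i],
            ambient=ambient,
            overdispersion=s["a"][i],
        )


# ---------------------------------------------------------------------------
# Gene filtering and module-count heuristic
# ---------------------------------------------------------------------------


def filter_genes(data: CountData, n_top: int = 3000, min_counts: int = 20) -> CountData:
    """Keep the ``n_top`` most variable genes with at least ``min_counts``.

    Total (spliced + unspliced) counts define detection; variability is the
    dispersion (variance / mean) of depth-normalized total expression.  Gene
    order of the survivors is preserved.
    """
    total = data.unspliced + data.spliced
    per_gene = total.sum(axis=0)
    detected = per_gene >= min_counts
    if detected.sum() < 2:
        raise ValueError(
            f"fewer than 2 genes have >= {min_counts} detected counts"
        )
    depth = total.sum(axis=1).astype(float)
    depth = np.where(depth == 0, 1.0, depth)
    norm = total / depth[:, None] * np.median(depth)
    mean = norm.mean(axis=0)
    disp = np.where(mean > 0, norm.var(axis=0) / np.where(mean > 0, mean, 1.0), 0.0)
    disp = np.where(detected, disp, -np.inf)
    order = np.argsort(-disp, kind="stable")
    keep_idx = np.sort(order[: min(n_top, int(detected.sum()))])
    return data.subset_genes(keep_idx)


def select_num_modules(
    data: CountData, n_modules: Optional[int] = None, resolution: float = 0.1, cap: int = 20
) -> int:
    """Default heuristic for the number of modules.

    A user-supplied value is always honored.  Otherwise: the number of
    Leiden partitions of a kNN graph over PCA-reduced log-normalized spliced
    counts, plus one, capped at ``cap`` — a cheap proxy for the number of
    distinct expression programs, documented as replaceable.
    """
    if n_modules is not None:
        return int(n_modules)
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    s = data.spliced.astype(float)
    depth = s.sum(axis=1)
    depth = np.where(depth == 0, 1.0, depth)
    x = np.log1p(s / depth[:, None] * np.median(depth))
    n_comp = int(min(30, x.shape[0] - 1, x.shape[1] - 1))
    if n_comp >= 2:
        x = PCA(n_components=n_comp, random_state=0).fit_transform(x)
    k = min(15, x.shape[0] - 1)
    adj = kneighbors_graph(x, n_neighbors=k, include_self=False)
    sources, targets = adj.nonzero()
    g = igraph.Graph(n=x.shape[0], edges=list(zip(sources, targets)))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=0,
    )
    return int(np.clip(len(set(part.membership)) + 1, 1, cap))


def posterior_time_cv(bundle: PosteriorBundle) -> np.ndarray:
    """Per-cell coefficient of variation (sample sd / mean) of posterior time.

    Uses the n-1 divisor for the sample standard deviation.  Cells with a
    zero mean (degenerate) get NaN rather than raising.
    """
    t = bundle.samples["t"]
    if t.shape[0] < 2:
        raise ValueError("posterior CV needs at least 2 samples")
    mean = t.mean(axis=0)
    sd = t.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv


# ---------------------------------------------------------------------------
# The variational model
# ---------------------------------------------------------------------------


class _Model:
    """Holds data tensors and computes the ELBO and its gradients."""

    def __init__(self, data: CountData, cfg: PriorConfig, n_modules: int):
        self.cfg = cfg
        self.M = n_modules
        self.C, self.G = data.spliced.shape
        self.X = data.stacked().astype(float)  # (C, G, 2)
        design = data.batch_design()
        self.E = design.n_batches
        self.batch_idx = design.batch_index
        infer_amb = cfg.infer_ambient
        self.infer_ambient = (self.E > 1) if infer_amb is None else bool(infer_amb)

        # prior log-space (mean, sd); hyper-linked groups handled separately
        tm = cfg.t_max
        self.prior = {
            "t": (np.log(tm / 2.0), cfg.time_sigma),
            "l_cell": (0.0, cfg.detection_cell_sigma),
            "l_mod": (0.0, cfg.detection_modality_sigma),
            "lam_on": cfg.lam_prior,
            "lam_off": cfg.lam_prior,
            "t_on": (np.log(tm / 4.0), cfg.switch_on_sigma),
            "dt": (np.log(tm / 2.0), cfg.switch_len_sigma),
            "mu_beta": cfg.rate_hyper,
            "mu_gamma": cfg.rate_hyper,
            "mu_ahat": cfg.target_hyper,
            "soup": cfg.ambient_prior,
        }
        self.shapes = {
            "t": (self.C,),
            "l_cell": (self.C,),
            "l_mod": (2,),
            "beta": (self.G,),
            "gamma": (self.G,),
            "a": (self.G, 2),
            "ahat": (self.M, self.G),
            "lam_on": (self.M,),
            "lam_off": (self.M,),
            "t_on": (self.M,),
            "dt": (self.M,),
            "mu_beta": (1,),
            "mu_gamma": (1,),
            "mu_ahat": (1,),
        }
        if self.infer_ambient:
            self.shapes["soup"] = (self.E, self.G, 2)

    # -- initialization ----------------------------------------------------

    def init_variational(self, orientation: int = 1):
        cfg, C, G, M = self.cfg, self.C, self.G, self.M
        total = self.X.sum(axis=2)  # (C, G)
        depth = total.sum(axis=1)
        depth = np.where(depth == 0, 1.0, depth)
        s_counts = self.X[..., 1]
        logx = np.log1p(s_counts / depth[:, None] * np.median(depth))
        logx = logx - logx.mean(axis=0)
        # leading principal component orders cells along the dominant axis
        if cfg.time_init == "flat":
            m_t = np.full(C, np.log(cfg.t_max / 2.0))
        else:
            u_svd, sv, _ = np.linalg.svd(logx, full_matrices=False)
            score = orientation * u_svd[:, 0]
            ranks = np.argsort(np.argsort(score))
            m_t = np.log(cfg.t_max / 2.0) + 0.6 * ndtri((ranks + 0.5) / C)

        s_mean = np.maximum(s_counts.mean(axis=0), 1e-2)
        u_mean = np.maximum(self.X[..., 0].mean(axis=0), 1e-2)
        # moment-matched rate init: near steady state u/s ~ (l_u/l_s)(gamma/beta),
        # so the per-gene u/s ratio (relative to its global level) seeds the
        # gamma/beta split, and the global level seeds the modality detection
        global_ratio = max(self.X[..., 0].sum() / max(self.X[..., 1].sum(), 1.0), 1e-3)
        log_ratio = np.clip(np.log(u_mean / s_mean / global_ratio), -2.5, 2.5)
        m_beta = np.full(G, np.log(0.5))
        m_gamma = m_beta + log_ratio
        m = {
            "t": m_t,
            "l_cell": np.log(depth / np.median(depth)) * 0.5,
            "l_mod": np.array([np.log(global_ratio), 0.0]),
            "beta": m_beta,
            "gamma": m_gamma,
            "a": np.full((G, 2), np.log(8.0)),
            "ahat": np.tile(np.log(0.45 * s_mean / M + 1e-3), (M, 1)),
            "lam_on": np.full(M, np.log(1.5)),
            "lam_off": np.full(M, np.log(1.5)),
            "t_on": np.log(cfg.t_max * np.linspace(0.08, 0.4, M)),
            "dt": np.full(M, np.log(0.4 * cfg.t_max)),
            "mu_beta": np.array([np.log(0.5)]),
            "mu_gamma": np.array([np.log(0.5)]),
            "mu_ahat": np.array([np.log(0.3)]),
        }
        log_s = {k: np.full(self.shapes[k], -2.0) for k in self.shapes}
        log_s["t"] = np.full((C,), np.log(0.3))
        if self.infer_ambient:
            m["soup"] = np.full((self.E, G, 2), np.log(0.02))
        return m, log_s

    # -- log joint + gradients --------------------------------------------

    def _kinetics_stack(self, th, full: bool = True):
        """Biological expectations for the base point and FD perturbations.

        Returns per-module components u, s with shape (P, C, M, G); eval 0 is
        the base point, the following evals perturb (in log space, by
        _FD_EPS): t, beta, gamma, ahat and — when ``full`` — the module
        scalars lam_on, lam_off, t_on, dt.  Note that perturbing t_on moves
        the whole ON window (t_off = t_on + dt).
        """
        P = 9 if full else 5
        bump = np.exp(_FD_EPS)

        def stack(base, pert_idx):
            out = np.broadcast_to(base, (P,) + base.shape).copy()
            if pert_idx < P:
                out[pert_idx] = base * bump
            return out

        C, M, G = self.C, self.M, self.G
        u = np.empty((P, C, M, G))
        s = np.empty((P, C, M, G))
        _fastkin.stack_components(
            stack(th["t"], 1),
            stack(th["beta"], 2),
            stack(th["gamma"], 3),
            stack(th["ahat"], 4),
            stack(th["lam_on"], 5),
            stack(th["lam_off"], 6),
            stack(th["t_on"], 7),
            stack(th["dt"], 8),
            u,
            s,
        )
        return u, s

    def logjoint_and_grads(self, x, th, full: bool = True):
        """Single-sample log joint and its gradient in unconstrained space.

        With ``full=False`` the (cheap-to-skip) gradients of the per-module
        scalars are omitted; the optimizer then leaves them untouched for
        that step.
        """
        C, G, M = self.C, self.G, self.M
        X = self.X
        u_st, s_st = self._kinetics_stack(th, full=full)  # (P, C, M, G)
        xb = np.stack([u_st[0].sum(axis=1), s_st[0].sum(axis=1)], axis=-1)  # (C,G,2)

        l = th["l_cell"][:, None, None] * th["l_mod"]  # (C,1,2)
        if self.infer_ambient:
            soup = th["soup"][self.batch_idx]  # (C,G,2)
        else:
            soup = 0.0
        a = th["a"]  # (G,2)
        mu = l * (soup + xb) + _MU_EPS

        # full NB log-likelihood at the base point
        ll = (
            gammaln(X + a)
            - gammaln(a)
            - gammaln(X + 1.0)
            + a * np.log(a / (a + mu))
            + X * np.log(mu / (a + mu))
        )
        loglik = float(ll.sum())

        dlldmu = X / mu - (X + a) / (a + mu)  # (C,G,2)
        w = dlldmu * l  # chain to (soup + xB)-space

        grads = {}
        # finite-difference gradients through the kinetics
        du = u_st[1:] - u_st[0]  # (8, C, M, G)
        ds = s_st[1:] - s_st[0]
        g_t = np.empty(C)
        g_beta = np.empty(G)
        g_gamma = np.empty(G)
        g_ahat = np.empty((M, G))
        g_mod = np.empty((4, M))
        _fastkin.fd_gradients(
            du,
            ds,
            np.ascontiguousarray(w[..., 0]),
            np.ascontiguousarray(w[..., 1]),
            1.0 / _FD_EPS,
            g_t,
            g_beta,
            g_gamma,
            g_ahat,
            g_mod,
        )
        grads["t"] = g_t
        grads["beta"] = g_beta
        grads["gamma"] = g_gamma
        grads["ahat"] = g_ahat
        if full:
            grads["lam_on"] = g_mod[0]
            grads["lam_off"] = g_mod[1]
            grads["t_on"] = g_mod[2]
            grads["dt"] = g_mod[3]

        # analytic gradients for measurement parameters (in log space)
        dll_dmu_mu = dlldmu * mu
        grads["l_cell"] = dll_dmu_mu.sum(axis=(1, 2))
        grads["l_mod"] = dll_dmu_mu.sum(axis=(0, 1))
        if self.infer_ambient:
            g_soup = np.zeros((self.E, G, 2))
            np.add.at(g_soup, self.batch_idx, w)
            grads["soup"] = g_soup * th["soup"]
        dllda = (
            digamma(X + a) - digamma(a) + np.log(a / (a + mu)) + 1.0 - (X + a) / (a + mu)
        )
        grads["a"] = dllda.sum(axis=0) * a

        # priors (Normal in log space; hierarchical hyper-means; gamma for a)
        logprior = 0.0
        for name in self.shapes:
            if name == "a":
                k_shape, k_rate = self.cfg.overdispersion_gamma
                logprior += float(
                    (k_shape * x["a"] - k_rate * th["a"]).sum()
                )
                grads["a"] = grads["a"] + k_shape - k_rate * th["a"]
                continue
            if name in ("beta", "gamma", "ahat"):
                hyper = {"beta": "mu_beta", "gamma": "mu_gamma", "ahat": "mu_ahat"}[name]
                mu0 = x[hyper]
                sd = self.cfg.rate_sigma if name != "ahat" else self.cfg.target_sigma
            else:
                mu0, sd = self.prior[name]
            resid = (x[name] - mu0) / sd
            logprior += float(-0.5 * (resid ** 2).sum())
            grads[name] = grads.get(name, 0.0) - resid / sd
            if name in ("beta", "gamma", "ahat"):
                hyper = {"beta": "mu_beta", "gamma": "mu_gamma", "ahat": "mu_ahat"}[name]
                grads[hyper] = grads.get(hyper, 0.0) + (resid / sd).sum()
        if not np.isfinite(loglik):
            raise FitDivergence("non-finite likelihood; check input counts and config")
        return loglik + logprior, grads


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params, grads, lr, keys=None):
        self.t += 1
        b1, b2, eps = 0.9, 0.99, 1e-8
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k in keys if keys is not None else params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] = params[k] + lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + eps
            )


def _run_svi(model: _Model, m, log_s, epochs, rng, lr0, lr_decay, average_frac=0.0):
    """Adam on the single-sample reparameterized ELBO.

    ``average_frac``: Polyak-average the variational parameters over the last
    fraction of steps — weakly identified coordinates wander under gradient
    noise long after the ELBO has plateaued, and the running mean of the
    iterates is a far better estimate of the optimum than the last iterate.
    """
    shapes = model.shapes
    opt_m = _Adam(shapes, lr0)
    opt_s = _Adam(shapes, lr0)
    n_latent = sum(int(np.prod(s)) if s else 1 for s in shapes.values())
    ent_const = 0.5 * n_latent * np.log(2.0 * np.pi * np.e)
    trace = np.empty(epochs)
    avg_start = epochs - int(average_frac * epochs)
    avg_m = {k: np.zeros(shapes[k]) for k in shapes} if average_frac > 0 else None
    avg_s = {k: np.zeros(shapes[k]) for k in shapes} if average_frac > 0 else None
    n_avg = 0
    scalar_keys = ("lam_on", "lam_off", "t_on", "dt")
    for step in range(epochs):
        lr = lr0 * lr_decay ** (step / max(epochs - 1, 1))
        # module-scalar gradients are comparatively expensive and slowly
        # varying: refresh them every other step
        full = step % 2 == 0
        keys = list(shapes) if full else [k for k in shapes if k not in scalar_keys]
        z = {k: rng.standard_normal(shapes[k]) for k in shapes}
        s = {k: np.exp(log_s[k]) for k in shapes}
        x = {k: m[k] + s[k] * z[k] for k in shapes}
        th = {k: np.exp(x[k]) for k in shapes if not k.startswith("mu_")}
        logp, grads = model.logjoint_and_grads(x, th, full=full)
        entropy = ent_const + sum(float(log_s[k].sum()) for k in shapes)
        trace[step] = logp + entropy
        if not np.isfinite(trace[step]):
            raise FitDivergence(f"ELBO diverged at step {step}")
        g_s = {k: grads[k] * z[k] * s[k] + 1.0 for k in keys}
        opt_m.step(m, grads, lr, keys)
        opt_s.step(log_s, g_s, lr, keys)
        for k in keys:
            np.clip(log_s[k], -6.0, 1.0, out=log_s[k])
        if avg_m is not None and step >= avg_start:
            n_avg += 1
            for k in shapes:
                avg_m[k] += m[k]
                avg_s[k] += log_s[k]
    if avg_m is not None and n_avg > 0:
        m = {k: avg_m[k] / n_avg for k in shapes}
        log_s = {k: avg_s[k] / n_avg for k in shapes}
    return m, log_s, trace


def fit(
    data: CountData,
    config: Optional[PriorConfig] = None,
    seed: int = 0,
    epochs: Optional[int] = None,
) -> PosteriorBundle:
    """Fit the model to raw counts and return joint posterior samples.

    Runs two short pilot optimizations with opposite time orientations, then
    continues the better one for the full schedule.  Identical
    (data, config, seed) give bitwise-identical results.
    """
    cfg = config or PriorConfig()
    n_modules = select_num_modules(data, cfg.n_modules)
    if n_modules > data.n_cells:
        raise ValueError("n_modules cannot exceed the number of cells")
    epochs = int(cfg.epochs if epochs is None else epochs)
    model = _Model(data, cfg, n_modules)

    seeds = np.random.SeedSequence(seed).spawn(4)
    pilots = {}
    pilot_epochs = min(cfg.pilot_epochs, epochs)
    for i, orientation in enumerate((1, -1)):
        m0, s0 = model.init_variational(orientation)
        rng = np.random.default_rng(seeds[i])
        m1, s1, tr = _run_svi(model, m0, s0, pilot_epochs, rng, cfg.learning_rate, 1.0)
        pilots[orientation] = (m1, s1, tr)
    scores = {o: pilots[o][2][-max(pilot_epochs // 5, 1):].mean() for o in pilots}
    orientation = 1 if scores[1] >= scores[-1] else -1
    m, log_s, _ = pilots[orientation]

    rng = np.random.default_rng(seeds[2])
    m, log_s, trace = _run_svi(
        model, m, log_s, epochs, rng, cfg.learning_rate, cfg.lr_decay,
        average_frac=cfg.average_frac,
    )

    # draw joint posterior samples from the fitted variational distribution
    rng_post = np.random.default_rng(seeds[3])
    S = cfg.num_posterior_samples
    samples = {}
    for k in model.shapes:
        if k.startswith("mu_"):
            continue
        z = rng_post.standard_normal((S,) + model.shapes[k])
        samples[k] = np.exp(m[k] + np.exp(log_s[k]) * z)
    samples["t_off"] = samples["t_on"] + samples["dt"]
    del samples["dt"]

    return PosteriorBundle(
        samples=samples,
        elbo_trace=trace,
        seed=seed,
        n_modules=n_modules,
        t_max=cfg.t_max,
        gene_names=data.gene_names,
        cell_names=data.cell_names,
        time_orientation=orientation,
        extras={"epochs": epochs, "pilot_elbo": {int(k): float(v) for k, v in scores.items()}},
    )
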