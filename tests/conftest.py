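"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from modvelo.kinetics import GeneRates, ModuleKinetics


def integrate_modules(kinetics: ModuleKinetics, rates: GeneRates, times):
    """Adaptive numerical integration of the module ODE system.

    Independent oracle for the closed forms: integrates
    d alpha/dt = lam * (target - alpha), du/dt = alpha - beta u,
    ds/dt = beta u - gamma s for every module x gene from zero initial
    conditions at each module's switch-on time, and returns per-module
    components with shape (len(times), M, G).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    m, g = kinetics.target_rate.shape
    out = np.zeros((3, times.size, m, g))
    t_end = float(times.max())
    for mi in range(m):
        lam_on = kinetics.activation_rate[mi]
        lam_off = kinetics.deactivation_rate[mi]
        t_on = kinetics.switch_on[mi]
        t_off = kinetics.switch_off[mi]

        def rhs(t, y, mi=mi, lam_on=lam_on, lam_off=lam_off, t_on=t_on, t_off=t_off):
            a, u, s = y.reshape(3, -1)
            if t < t_on:
                return np.zeros_like(y)
            on = t < t_off
            target = kinetics.target_rate[mi] if on else 0.0
            lam = lam_on if on else lam_off
            da = lam * (target - a)
            du = a - rates.splicing * u
            ds = rates.splicing * u - rates.degradation * s
            return np.concatenate([da, du, ds])

        sol = solve_ivp(
            rhs,
            (0.0, max(t_end, t_on) + 1e-9),
            np.zeros(3 * g),
            t_eval=np.clip(times, 0.0, None),
            rtol=1e-10,
            atol=1e-12,
            max_step=max((t_off - t_on) / 10 if np.isfinite(t_off) else t_end, 1e-3),
            dense_output=False,
            method="LSODA",
        )
        out[:, :, mi, :] = sol.y.reshape(3, g, -1).transpose(0, 2, 1)
    return out[0], out[1], out[2]


def random_kinetics(rng, n_modules=3, n_genes=3, degenerate=None):
    """Random but well-scaled kinetic parameters for oracle comparisons.

    ``degenerate`` optionally forces near-equal rate pairs: one of
    "beta_gamma", "lam_beta", "lam_gamma" plus a relative gap (e.g. 0.0,
    1e-6, 1e-3).
    """
    beta = rng.uniform(0.2, 2.0, n_genes)
    gamma = rng.uniform(0.2, 2.0, n_genes)
    lam_on = rng.uniform(0.5, 4.0, n_modules)
    lam_off = rng.uniform(0.5, 4.0, n_modules)
    if degenerate is not None:
        kind, gap = degenerate
        if kind == "beta_gamma":
            gamma = beta * (1.0 + gap)
        elif kind == "lam_beta":
            lam_on = np.full(n_modules, beta[0] * (1.0 + gap))
        elif kind == "lam_gamma":
            lam_on = np.full(n_modules, gamma[0] * (1.0 + gap))
        else:  # pragma: no cover
            raise ValueError(kind)
    t_on = np.sort(rng.uniform(0.0, 3.0, n_modules))
    t_off = t_on + rng.uniform(0.5, 4.0, n_modules)
    kin = ModuleKinetics(
        target_rate=rng.uniform(0.1, 3.0, (n_modules, n_genes)),
        activation_rate=lam_on,
        deactivation_rate=lam_off,
        switch_on=t_on,
        switch_off=t_off,
    )
    return kin, GeneRates(splicing=beta, degradation=gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
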