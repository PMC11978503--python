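"""Closed-form kinetics of modular transcription dynamics.

The transcription rate of every gene is a superposition of ``M`` independent
modules.  While a module is ON (between its switch-on and switch-off time) its
transcription rate relaxes toward a gene-specific target rate ``alpha_hat`` at
rate ``lam_on``; after switch-off the rate decays exponentially at rate
``lam_off``.  Unspliced RNA is produced at the transcription rate and spliced
at rate ``beta``; spliced RNA degrades at rate ``gamma``:

    d alpha_mg / dt = lam_mi * (alpha_hat_mgi - alpha_mg)
    d u_mg     / dt = alpha_mg - beta_g * u_mg
    d s_mg     / dt = beta_g * u_mg - gamma_g * s_mg

with ``alpha_hat = 0`` in the OFF state and ``alpha = u = s = 0`` at the
module's switch-on time.  This linear cascade is solved exactly: the solution
in each phase is a linear combination of exponentials whose coefficients are
divided differences of ``exp(-r*t)`` over the rate constants involved.
Divided differences are evaluated with a confluent-safe algorithm, so nearly
equal rates (``lam ~ beta``, ``beta ~ gamma``, ...) never cause catastrophic
cancellation and no case analysis leaks into the public API.

Everything here is pure (elementwise) vectorized math over
``cells x modules x genes``; the inference, simulation and downstream layers
all evaluate their expectations through this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModuleKinetics",
    "GeneRates",
    "BiologicalExpectation",
    "module_alpha",
    "module_unspliced",
    "module_spliced",
    "module_components",
    "expected_counts",
    "velocity",
]

# Below this value of (node spread) * t, divided differences switch to a
# truncated Taylor expansion around the node mean; the two branches overlap
# with ~1e-13 relative accuracy.
_TAYLOR_THRESHOLD = 1e-3


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ModuleKinetics:
    """Per-module kinetic parameters.

    Parameters
    ----------
    target_rate
        ``(M, G)`` array of ON-state target transcription rates
        (counts / unit time); the OFF-state target rate is identically zero.
    activation_rate, deactivation_rate
        ``(M,)`` relaxation rates ``lam`` toward the ON / away from the OFF
        target (1 / unit time), shared across genes.
    switch_on, switch_off
        ``(M,)`` module switch times on the shared trajectory timescale;
        ``switch_on < switch_off`` (``switch_off`` may be ``+inf``).
    """

    target_rate: np.ndarray
    activation_rate: np.ndarray
    deactivation_rate: np.ndarray
    switch_on: np.ndarray
    switch_off: np.ndarray

    def __post_init__(self) -> None:
        self.target_rate = np.atleast_2d(np.asarray(self.target_rate, dtype=float))
        for name in ("activation_rate", "deactivation_rate", "switch_on", "switch_off"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        m = self.target_rate.shape[0]
        if m < 1:
            raise ValueError("at least one module is required")
        for name in ("activation_rate", "deactivation_rate", "switch_on", "switch_off"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
        if np.any(self.target_rate < 0):
            raise ValueError("target_rate must be >= 0")
        if np.any(self.activation_rate <= 0) or np.any(self.deactivation_rate <= 0):
            raise ValueError("activation/deactivation rates must be > 0")
        if not np.all(self.switch_on < self.switch_off):
            raise ValueError("switch_on must be < switch_off for every module")
        if not np.all(np.isfinite(self.switch_on)):
            raise ValueError("switch_on must be finite")

    @property
    def n_modules(self) -> int:
        return self.target_rate.shape[0]

    @property
    def n_genes(self) -> int:
        return self.target_rate.shape[1]


@dataclass
class GeneRates:
    """Per-gene splicing (``beta``) and degradation (``gamma``) rates."""

    splicing: np.ndarray
    degradation: np.ndarray

    def __post_init__(self) -> None:
        self.splicing = np.atleast_1d(np.asarray(self.splicing, dtype=float))
        self.degradation = np.atleast_1d(np.asarray(self.degradation, dtype=float))
        if self.splicing.shape != self.degradation.shape:
            raise ValueError("splicing and degradation must have the same shape")
        if np.any(self.splicing <= 0) or np.any(self.degradation <= 0):
            raise ValueError("rates must be > 0")

    @property
    def n_genes(self) -> int:
        return self.splicing.shape[0]


@dataclass
class BiologicalExpectation:
    """Expected counts before measurement effects.

    ``unspliced`` / ``spliced`` are the ``(C, G)`` totals; the per-module
    components (``C, M, G``) satisfy superposition: totals are exact sums of
    the components.
    """

    unspliced: np.ndarray
    spliced: np.ndarray
    unspliced_components: np.ndarray
    spliced_components: np.ndarray
    alpha_components: np.ndarray

    @property
    def transcription_rate(self) -> np.ndarray:
        """Total transcription rate per cell x gene."""
        return self.alpha_components.sum(axis=-3)


# ---------------------------------------------------------------------------
# Confluent-safe divided differences of exp(-r * t)
# ---------------------------------------------------------------------------
#
# The closed forms are linear combinations of divided differences (DDs) of
# g(r) = exp(-r * tau) over the rate constants of the exponential cascade
# (0, lam, beta, gamma).  Naive Newton recursion divides by rate gaps, which
# loses precision when eigenvalues nearly coincide.  Stability is obtained by
#   * expm1 for pairs involving the zero node,
#   * a short centered Taylor series whenever (node spread) * tau is small
#     (which also covers exactly coincident rates and tau = 0),
#   * pivoting every recursion on the widest node pair (nodes sorted
#     elementwise), so no denominator is ever smaller than the spread that
#     the Taylor branch already guards.
# All operations are elementwise and broadcast, so the same code serves a
# single parameter set and the stacked evaluations of the inference loop.

_TAYLOR_THRESHOLD = 1e-7


def _pair_dd(ep, eq, p, q, tau):
    """DD of exp(-r tau) over {p, q}, exact for any gap.

    (e^{-p tau} - e^{-q tau}) / (p - q) = -tau e^{-q tau} expm1(x)/x with
    x = (q - p) tau; expm1 keeps full precision as x -> 0."""
    x = (q - p) * tau
    small = np.abs(x) < 0.5  # cancellation regime; also avoids expm1 overflow
    xs = np.where(small, x, 0.0)
    ratio = np.expm1(xs) / np.where(xs == 0.0, 1.0, xs)
    exact = -tau * eq * np.where(xs == 0.0, 1.0, ratio)
    direct = (ep - eq) / np.where(small, 1.0, p - q)
    return np.where(small, exact, direct)


def _zero_pair_dd(er, r, tau):
    """DD over {0, r}: expm1(-r tau) / r, stable for any r > 0."""
    return np.expm1(-r * tau) / r


def _sort3(r1, r2, r3, e1, e2, e3):
    """Elementwise ascending sort of three rates with their exponentials."""
    lo12 = np.minimum(r1, r2)
    hi12 = np.maximum(r1, r2)
    a = np.minimum(lo12, r3)
    c = np.maximum(hi12, r3)
    b = (r1 + r2 + r3) - a - c
    swap12 = r1 > r2
    e_lo12 = np.where(swap12, e2, e1)
    e_hi12 = np.where(swap12, e1, e2)
    ea = np.where(r3 < lo12, e3, e_lo12)
    ec = np.where(r3 > hi12, e3, e_hi12)
    mid_is_3 = (r3 >= lo12) & (r3 <= hi12)
    eb = np.where(mid_is_3, e3, np.where(r3 < lo12, e_lo12, e_hi12))
    return a, b, c, ea, eb, ec


def _triple_dd(a, b, c, ea, eb, ec, tau):
    """DD over ascending {a, b, c} via the widest pivot (c - a)."""
    g_ab = _pair_dd(ea, eb, a, b, tau)
    g_bc = _pair_dd(eb, ec, b, c, tau)
    spread = c - a
    small = spread * tau < _TAYLOR_THRESHOLD
    rec = (g_bc - g_ab) / np.where(small, 1.0, spread)
    tay = (ea + eb + ec) / 3.0 * 0.5 * tau * tau
    return np.where(small, tay, rec), g_ab


def _cascade_dds(r1, r2, r3, tau, e1, e2, e3):
    """DDs over {0, r1, r2} and {0, r1, r2, r3} for the full cascade.

    Returns (dd3, dd4).  dd3 keeps the *unsorted* node identity {0, r1, r2}
    (DDs are symmetric, so sorting r1, r2 internally is harmless); dd4 sorts
    all three rates to pivot on the widest gaps.
    """
    # dd3 over {0, min(r1,r2), max(r1,r2)}
    p = np.minimum(r1, r2)
    q = np.maximum(r1, r2)
    ep = np.where(r1 <= r2, e1, e2)
    eq = np.where(r1 <= r2, e2, e1)
    g_0p = _zero_pair_dd(ep, p, tau)
    g_pq = _pair_dd(ep, eq, p, q, tau)
    small3 = q * tau < _TAYLOR_THRESHOLD
    rec3 = (g_pq - g_0p) / np.where(small3, 1.0, q)
    tay3 = (1.0 + ep + eq) / 3.0 * 0.5 * tau * tau
    dd3 = np.where(small3, tay3, rec3)

    # dd4 over {0, a, b, c} with a <= b <= c
    a, b, c, ea, eb, ec = _sort3(r1, r2, r3, e1, e2, e3)
    g_abc, g_ab = _triple_dd(a, b, c, ea, eb, ec, tau)
    g_0a = _zero_pair_dd(ea, a, tau)
    small_0ab = b * tau < _TAYLOR_THRESHOLD
    rec_0ab = (g_ab - g_0a) / np.where(small_0ab, 1.0, b)
    tay_0ab = (1.0 + ea + eb) / 3.0 * 0.5 * tau * tau
    g_0ab = np.where(small_0ab, tay_0ab, rec_0ab)
    small4 = c * tau < _TAYLOR_THRESHOLD
    rec4 = (g_abc - g_0ab) / np.where(small4, 1.0, c)
    tay4 = -(1.0 + ea + eb + ec) / 4.0 * tau ** 3 / 6.0
    dd4 = np.where(small4, tay4, rec4)
    return dd3, dd4


# ---------------------------------------------------------------------------
# Phase-resolved closed forms
# ---------------------------------------------------------------------------


def _raw_components(tau_on, tau_off, ahat, lam_on, lam_off, beta, gamma):
    """Closed-form (alpha, u, s) for one module, broadcast elementwise.

    ``tau_on``   time elapsed inside the ON window (clipped to its length),
    ``tau_off``  time elapsed since switch-off (0 while ON or before ON).

    Phase 1 (ON): the cascade 1 -> lam_on -> beta -> gamma of unit exponential
    stages driven by a step gives

        alpha = ahat * (1 - exp(-lam_on tau))
        u     = ahat * lam_on        * dd(0, lam_on, beta)
        s     = -ahat * lam_on * beta * dd(0, lam_on, beta, gamma)

    Phase 2 (after switch-off) propagates the phase-1 terminal state through
    the homogeneous decay plus the convolution response to the decaying alpha.
    """
    e_l = np.exp(-lam_on * tau_on)
    e_b = np.exp(-beta * tau_on)
    e_g = np.exp(-gamma * tau_on)
    alpha1 = ahat * -np.expm1(-lam_on * tau_on)
    dd3, dd4 = _cascade_dds(lam_on, beta, gamma, tau_on, e_l, e_b, e_g)
    u1 = ahat * lam_on * dd3
    s1 = -ahat * lam_on * beta * dd4

    dec_a = np.exp(-lam_off * tau_off)
    dec_b = np.exp(-beta * tau_off)
    dec_g = np.exp(-gamma * tau_off)
    # convolutions of 2 resp. 3 exponentials: -dd resp. +dd
    c_ab = -_pair_dd(dec_a, dec_b, lam_off, beta, tau_off)
    c_bg = -_pair_dd(dec_b, dec_g, beta, gamma, tau_off)
    a3, b3, c3, ea, eb, ec = _sort3(lam_off, beta, gamma, dec_a, dec_b, dec_g)
    c_abg = _triple_dd(a3, b3, c3, ea, eb, ec, tau_off)[0]

    alpha = alpha1 * dec_a
    u = u1 * dec_b + alpha1 * c_ab
    s = s1 * dec_g + beta * u1 * c_bg + beta * alpha1 * c_abg
    return alpha, u, s


def _phase_times(t, switch_on, switch_off):
    """Split absolute time into ON-window and post-OFF elapsed times."""
    window = switch_off - switch_on
    tau_on = np.clip(t - switch_on, 0.0, window)
    tau_off = np.maximum(t - switch_off, 0.0)
    # switch_off = +inf leaves tau_off = max(-inf, 0) = 0 and tau_on = t - T_on
    return tau_on, tau_off


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("cell times must be finite")
    return t


def module_components(t, kinetics: ModuleKinetics, rates: GeneRates):
    """Per-module (alpha, u, s) components, each shaped ``(..., M, G)``.

    ``t`` may be a scalar or an array of cell times; a trailing
    ``modules x genes`` block is appended to its shape.
    """
    t = _check_times(t)
    tt = t[..., None, None]
    ahat = kinetics.target_rate
    lam_on = kinetics.activation_rate[:, None]
    lam_off = kinetics.deactivation_rate[:, None]
    tau_on, tau_off = _phase_times(
        tt, kinetics.switch_on[:, None], kinetics.switch_off[:, None]
    )
    return _raw_components(
        tau_on, tau_off, ahat, lam_on, lam_off, rates.splicing, rates.degradation
    )


def module_alpha(t, kinetics: ModuleKinetics) -> np.ndarray:
    """Transcription-rate component ``alpha_mg(t)`` of every module."""
    t = _check_times(t)
    tt = t[..., None, None]
    lam_on = kinetics.activation_rate[:, None]
    lam_off = kinetics.deactivation_rate[:, None]
    tau_on, tau_off = _phase_times(
        tt, kinetics.switch_on[:, None], kinetics.switch_off[:, None]
    )
    alpha1 = kinetics.target_rate * -np.expm1(-lam_on * tau_on)
    return alpha1 * np.exp(-lam_off * tau_off)


def module_unspliced(t, kinetics: ModuleKinetics, rates: GeneRates) -> np.ndarray:
    """Expected unspliced counts ``u_mg(t)`` produced by each module."""
    return module_components(t, kinetics, rates)[1]


def module_spliced(t, kinetics: ModuleKinetics, rates: GeneRates) -> np.ndarray:
    """Expected spliced counts ``s_mg(t)`` produced by each module."""
    return module_components(t, kinetics, rates)[2]


def expected_counts(t, kinetics: ModuleKinetics, rates: GeneRates) -> BiologicalExpectation:
    """Biological expectation values: module components and their totals."""
    if kinetics.n_modules < 1:
        raise ValueError("at least one module is required")
    alpha, u, s = module_components(t, kinetics, rates)
    return BiologicalExpectation(
        unspliced=u.sum(axis=-2),
        spliced=s.sum(axis=-2),
        unspliced_components=u,
        spliced_components=s,
        alpha_components=alpha,
    )


def velocity(t, kinetics: ModuleKinetics, rates: GeneRates) -> np.ndarray:
    """RNA velocity ``ds/dt = sum_m (beta u_mg - gamma s_mg)`` per cell x gene."""
    _, u, s = module_components(t, kinetics, rates)
    return (rates.splicing * u - rates.degradation * s).sum(axis=-2)
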