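"""Fused numba kernels for the inference hot loop.

Scalar re-implementation of the closed-form module kinetics in
:mod:`modvelo.kinetics`, specialized for the stacked finite-difference
evaluations of the SVI step: one pass computes per-module unspliced/spliced
components for the base point and all perturbed parameter copies, skipping
whole phases when a cell sits before a module's switch-on or switch-off.
Equivalence with the reference numpy implementation is asserted in the test
suite; this module contains no independent modeling decisions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_THR = 1e-7  # Taylor threshold, matches kinetics._TAYLOR_THRESHOLD


@njit(cache=True, fastmath=True)
def _pair(ep, eq, p, q, tau):
    # corrected midpoint rule in the cancellation regime: the relative error
    # of -(ep+eq)/2 * tau * (1 - x^2/12) is O(x^4), far below the
    # finite-difference resolution of the SVI gradients
    x = (q - p) * tau
    if abs(x) < 1e-2:
        return -0.5 * (ep + eq) * tau * (1.0 - x * x / 12.0)
    return (ep - eq) / (p - q)


@njit(cache=True, fastmath=True)
def _triple_sorted(a, b, c, ea, eb, ec, tau):
    g_ab = _pair(ea, eb, a, b, tau)
    g_bc = _pair(eb, ec, b, c, tau)
    spread = c - a
    if spread * tau < _THR:
        return (ea + eb + ec) / 3.0 * 0.5 * tau * tau
    return (g_bc - g_ab) / spread


@njit(cache=True, fastmath=True)
def _cascade(lam, beta, gamma, tau, e_l, e_b, e_g):
    """(dd3, dd4) over {0, lam, beta} and {0, lam, beta, gamma}."""
    if lam <= beta:
        p, q, ep, eq = lam, beta, e_l, e_b
    else:
        p, q, ep, eq = beta, lam, e_b, e_l
    g_0p = np.expm1(-p * tau) / p
    g_pq = _pair(ep, eq, p, q, tau)
    if q * tau < _THR:
        dd3 = (1.0 + ep + eq) / 3.0 * 0.5 * tau * tau
    else:
        dd3 = (g_pq - g_0p) / q

    # ascending sort of (lam, beta, gamma) with exponentials
    a, b, c = lam, beta, gamma
    ea, eb, ec = e_l, e_b, e_g
    if a > b:
        a, b, ea, eb = b, a, eb, ea
    if b > c:
        b, c, eb, ec = c, b, ec, eb
    if a > b:
        a, b, ea, eb = b, a, eb, ea
    g_abc = _triple_sorted(a, b, c, ea, eb, ec, tau)
    g_0a = np.expm1(-a * tau) / a
    g_ab = _pair(ea, eb, a, b, tau)
    if b * tau < _THR:
        g_0ab = (1.0 + ea + eb) / 3.0 * 0.5 * tau * tau
    else:
        g_0ab = (g_ab - g_0a) / b
    if c * tau < _THR:
        dd4 = -(1.0 + ea + eb + ec) / 4.0 * tau ** 3 / 6.0
    else:
        dd4 = (g_abc - g_0ab) / c
    return dd3, dd4


@njit(cache=True, fastmath=True)
def stack_components(t, beta, gamma, ahat, lam_on, lam_off, t_on, dt, u_out, s_out):
    """Fill u_out, s_out of shape (P, C, M, G) with module components.

    Parameter arrays carry a leading evaluation axis P (finite-difference
    copies): t (P, C); beta, gamma (P, G); ahat (P, M, G); lam_on, lam_off,
    t_on, dt (P, M).
    """
    P, C = t.shape
    M = lam_on.shape[1]
    G = beta.shape[1]
    u1w = np.empty(G)
    s1w = np.empty(G)
    for p in range(P):
        for m in range(M):
            ton = t_on[p, m]
            window = dt[p, m]
            lon = lam_on[p, m]
            loff = lam_off[p, m]
            # the phase-1 terminal state at the end of the ON window is shared
            # by every cell past switch-off: hoist it out of the cell loop
            finite = np.isfinite(window)
            act_w = 0.0
            if finite:
                e_lw = np.exp(-lon * window)
                act_w = -np.expm1(-lon * window)
                for g in range(G):
                    bg = beta[p, g]
                    gg = gamma[p, g]
                    e_b = np.exp(-bg * window)
                    e_g = np.exp(-gg * window)
                    dd3, dd4 = _cascade(lon, bg, gg, window, e_lw, e_b, e_g)
                    ah = ahat[p, m, g]
                    u1w[g] = ah * lon * dd3
                    s1w[g] = -ah * lon * bg * dd4
            for c in range(C):
                tc = t[p, c]
                if tc <= ton:
                    for g in range(G):
                        u_out[p, c, m, g] = 0.0
                        s_out[p, c, m, g] = 0.0
                elif finite and tc > ton + window:
                    tau2 = tc - ton - window
                    dec_a = np.exp(-loff * tau2)
                    for g in range(G):
                        bg = beta[p, g]
                        gg = gamma[p, g]
                        ah = ahat[p, m, g]
                        alpha1 = ah * act_w
                        dec_b = np.exp(-bg * tau2)
                        dec_g = np.exp(-gg * tau2)
                        c_ab = -_pair(dec_a, dec_b, loff, bg, tau2)
                        c_bg = -_pair(dec_b, dec_g, bg, gg, tau2)
                        a3, b3, c3 = loff, bg, gg
                        ea, eb, ec = dec_a, dec_b, dec_g
                        if a3 > b3:
                            a3, b3, ea, eb = b3, a3, eb, ea
                        if b3 > c3:
                            b3, c3, eb, ec = c3, b3, ec, eb
                        if a3 > b3:
                            a3, b3, ea, eb = b3, a3, eb, ea
                        c_abg = _triple_sorted(a3, b3, c3, ea, eb, ec, tau2)
                        u_out[p, c, m, g] = u1w[g] * dec_b + alpha1 * c_ab
                        s_out[p, c, m, g] = (
                            s1w[g] * dec_g + bg * u1w[g] * c_bg + bg * alpha1 * c_abg
                        )
                else:
                    tau1 = tc - ton
                    if tau1 > window:
                        tau1 = window
                    e_l = np.exp(-lon * tau1)
                    for g in range(G):
                        bg = beta[p, g]
                        gg = gamma[p, g]
                        e_b = np.exp(-bg * tau1)
                        e_g = np.exp(-gg * tau1)
                        dd3, dd4 = _cascade(lon, bg, gg, tau1, e_l, e_b, e_g)
                        ah = ahat[p, m, g]
                        u_out[p, c, m, g] = ah * lon * dd3
                        s_out[p, c, m, g] = -ah * lon * bg * dd4


@njit(cache=True, fastmath=True)
def fd_gradients(du, ds, wu, ws, inv_eps, g_t, g_beta, g_gamma, g_ahat, g_mod):
    """Reduce finite-difference deltas into per-group likelihood gradients.

    du, ds: (8, C, M, G) deltas for evals (t, beta, gamma, ahat, lam_on,
    lam_off, t_on, dt); wu, ws: (C, G) chain weights.  Outputs are filled in
    place: g_t (C,), g_beta/g_gamma (G,), g_ahat (M, G), g_mod (4, M).
    """
    n_evals, C, M, G = du.shape
    for c in range(C):
        acc = 0.0
        for m in range(M):
            for g in range(G):
                acc += wu[c, g] * du[0, c, m, g] + ws[c, g] * ds[0, c, m, g]
        g_t[c] = acc * inv_eps
    for g in range(G):
        acc_b = 0.0
        acc_g = 0.0
        for c in range(C):
            for m in range(M):
                acc_b += wu[c, g] * du[1, c, m, g] + ws[c, g] * ds[1, c, m, g]
                acc_g += wu[c, g] * du[2, c, m, g] + ws[c, g] * ds[2, c, m, g]
        g_beta[g] = acc_b * inv_eps
        g_gamma[g] = acc_g * inv_eps
    for m in range(M):
        for g in range(G):
            acc = 0.0
            for c in range(C):
                acc += wu[c, g] * du[3, c, m, g] + ws[c, g] * ds[3, c, m, g]
            g_ahat[m, g] = acc * inv_eps
    if n_evals >= 8:
        for i in range(4):
            for m in range(M):
                acc = 0.0
                for c in range(C):
                    for g in range(G):
                        acc += (
                            wu[c, g] * du[4 + i, c, m, g]
                            + ws[c, g] * ds[4 + i, c, m, g]
                        )
                g_mod[i, m] = acc * inv_eps
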