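"""Exact first derivatives of the penalized cost by an adjoint sweep.

The forward model is the chain

    slew --(cumulative sum)--> Gs --(gradient filter)--> realized gradient
        --(spin-domain recursion over all positions)--> b(z) --> penalties

Each raster interval applies a complex-linear SU(2) map to the state
(a, b), so the reverse sweep propagates the complex cotangent with the
conjugate-transposed step matrix while accumulating the parameter
derivatives Re(g^H (dM/dq) u).  The gradient with respect to the realized
gradient is pulled back through the transpose of the filter operator and
the transpose of the slew integration (a reversed cumulative sum).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .constants import GAMMA_1H
from .objective import (DesignProblem, PenaltyState, profile_from_controls,
                        wrap_angle)
from .waveforms import ControlVector

_TINY = 1e-300


def _psi_and_derivative(phi: np.ndarray):
    """sin(phi/2)/phi and its derivative, series-stabilized near 0."""
    small = np.abs(phi) < 1e-4
    phi_safe = np.where(small, 1.0, phi)
    half = 0.5 * phi
    psi = np.where(small, 0.5 - phi ** 2 / 48.0 + phi ** 4 / 3840.0,
                   np.sin(half) / phi_safe)
    dpsi = np.where(small, -phi / 24.0 + phi ** 3 / 960.0,
                    np.cos(half) / (2.0 * phi_safe)
                    - np.sin(half) / phi_safe ** 2)
    return psi, dpsi


def _terminal_cotangent(b: np.ndarray, problem: DesignProblem,
                        pen: PenaltyState) -> np.ndarray:
    """Packed gradient dJ/d(Re b) + i dJ/d(Im b) of the profile penalties."""
    p = pen.p
    delta = problem.space.delta
    e_out = problem.bounds.e_out
    e_in = problem.bounds.e_in
    e_p = problem.bounds.e_p
    in_mask, out_mask, per_slice = problem.domains()
    mag = np.abs(b) ** 2
    djdm = np.zeros(b.size)
    djdm[out_mask] = (delta * pen.mu_out / 2.0
                      * (mag[out_mask] / e_out) ** (p - 1) / e_out)
    djdm[in_mask] = (-delta * pen.mu_in / 2.0
                     * ((1.0 - mag[in_mask]) / e_in) ** (p - 1) / e_in)
    djdphi = np.zeros(b.size)
    phase = np.angle(b ** 2)
    for mask in per_slice:
        ph = phase[mask]
        phasors = np.exp(1j * ph)
        s_sum = np.sum(phasors)
        mean = np.angle(s_sum)
        dev = wrap_angle(ph - mean)
        base = delta * pen.mu_p / e_p * (dev / e_p) ** (p - 1)
        dmean = np.real(phasors / s_sum)  # d(mean)/d(phase_z)
        djdphi[mask] = base - np.sum(base) * dmean
    g_b = 2.0 * b * djdm
    active = np.abs(b) ** 2 > 1e-30
    g_b[active] = g_b[active] + 2j * b[active] / mag[active] * djdphi[active]
    return g_b


def cost_and_gradient(x: ControlVector, problem: DesignProblem,
                      pen: PenaltyState):
    """Cost breakdown and exact gradient from a single forward sweep."""
    from .objective import _cost_terms
    from .bloch import refocusing_profile

    grad_x, prof, grad, g_real, a_hist, b_hist = _forward(x, problem)
    mag, phase = refocusing_profile(prof)
    breakdown = _cost_terms(x, grad.gs, mag, phase, problem, pen)
    g = _reverse(x, problem, pen, prof, grad, g_real, a_hist, b_hist)
    return breakdown, g


def _forward(x: ControlVector, problem: DesignProblem):
    prof_states, grad, g_real = profile_from_controls(x, problem,
                                                      return_states=True)
    prof, a_hist, b_hist = prof_states
    if not np.all(np.isfinite(a_hist)) or not np.all(np.isfinite(b_hist)):
        raise FloatingPointError("non-finite state in forward sweep")
    return None, prof, grad, g_real, a_hist, b_hist


def gradient(x: ControlVector, problem: DesignProblem,
             pen: PenaltyState) -> ControlVector:
    """dJ/d(r, theta, s) at the controls ``x``; exact to rounding."""
    _, prof, grad, g_real, a_hist, b_hist = _forward(x, problem)
    return _reverse(x, problem, pen, prof, grad, g_real, a_hist, b_hist)


def _reverse(x: ControlVector, problem: DesignProblem, pen: PenaltyState,
             prof, grad, g_real, a_hist, b_hist) -> ControlVector:
    grid = x.grid
    tau = grid.tau
    n = grid.n_intervals
    z = problem.space.z
    k = GAMMA_1H * tau

    g_a = np.zeros(z.size, dtype=complex)
    g_b = _terminal_cotangent(prof.b, problem, pen)

    if _kernels.HAVE_NUMBA:
        djdr, djdtheta, djdgt = _kernels.reverse_sweep(
            np.ascontiguousarray(x.r), np.ascontiguousarray(x.theta),
            np.ascontiguousarray(g_real), np.ascontiguousarray(z),
            tau, GAMMA_1H, a_hist, b_hist,
            np.ascontiguousarray(g_b))
        return _assemble_control_gradient(x, problem, pen, grad, djdr,
                                          djdtheta, djdgt)

    b1 = x.r * np.exp(1j * x.theta)
    djdr = np.zeros(n)
    djdtheta = np.zeros(n)
    djdgt = np.zeros(n)  # w.r.t. the realized gradient

    for m in range(n - 1, -1, -1):
        a_prev = a_hist[m]
        b_prev = b_hist[m]
        w = z * g_real[m]
        r = x.r[m]
        q = np.sqrt(r * r + w * w)
        phi = -k * q
        psi, dpsi = _psi_and_derivative(phi)
        half = 0.5 * phi
        cos_half = np.cos(half)
        sin_half = np.sin(half)
        alpha = cos_half + 1j * k * w * psi
        beta = 1j * k * b1[m] * psi

        q_safe = np.maximum(q, _TINY)
        dphi_dr = -k * r / q_safe
        dphi_dw = -k * w / q_safe
        dalpha_dphi = -0.5 * sin_half + 1j * k * w * dpsi
        dbeta_dphi = 1j * k * b1[m] * dpsi

        dalpha_dr = dalpha_dphi * dphi_dr
        dbeta_dr = 1j * k * np.exp(1j * x.theta[m]) * psi \
            + dbeta_dphi * dphi_dr
        dalpha_dg = z * (1j * k * psi + dalpha_dphi * dphi_dw)
        dbeta_dg = z * dbeta_dphi * dphi_dw
        dbeta_dtheta = 1j * beta

        ga_c = np.conj(g_a)
        gb_c = np.conj(g_b)

        djdr[m] = np.sum(
            (ga_c * (dalpha_dr * a_prev - np.conj(dbeta_dr) * b_prev)
             + gb_c * (dbeta_dr * a_prev + np.conj(dalpha_dr) * b_prev)).real)
        djdtheta[m] = np.sum(
            (ga_c * (-np.conj(dbeta_dtheta) * b_prev)
             + gb_c * (dbeta_dtheta * a_prev)).real)
        djdgt[m] = np.sum(
            (ga_c * (dalpha_dg * a_prev - np.conj(dbeta_dg) * b_prev)
             + gb_c * (dbeta_dg * a_prev + np.conj(dalpha_dg) * b_prev)).real)

        # pull the cotangent back through the step: g <- M^H g
        g_a, g_b = (np.conj(alpha) * g_a + np.conj(beta) * g_b,
                    -beta * g_a + alpha * g_b)

    return _assemble_control_gradient(x, problem, pen, grad, djdr,
                                      djdtheta, djdgt)


def _assemble_control_gradient(x: ControlVector, problem: DesignProblem,
                               pen: PenaltyState, grad, djdr, djdtheta,
                               djdgt) -> ControlVector:
    tau = x.grid.tau
    # direct control terms
    djdr = djdr + tau * pen.mu_rf * x.r

    # realized gradient -> demanded gradient (filter transpose)
    op = problem.filter_op(x.grid)
    djdgs = djdgt if op is None else op.apply_transpose(djdgt)
    gmax = problem.hw.gmax
    djdgs = djdgs + tau * pen.mu_g / gmax * (grad.gs / gmax) ** (pen.p - 1)

    # demanded gradient -> slew (transpose of tau * cumulative sum)
    djds = tau * np.cumsum(djdgs[::-1])[::-1]

    return ControlVector(djdr, djdtheta, djds, x.grid)


def finite_difference_gradient(x: ControlVector, problem: DesignProblem,
                               pen: PenaltyState, indices,
                               rel_step: float = 3e-4) -> np.ndarray:
    """Central finite differences of the cost for selected packed indices.

    Independent verification path for the adjoint; kept deliberately
    simple and free of any code shared with :func:`gradient`.
    """
    from .objective import cost

    x0 = x.pack()
    out = np.zeros(len(indices))
    n = x.grid.n_intervals
    block_scale = np.concatenate([
        np.full(n, problem.hw.rmax),   # tesla-sized amplitudes
        np.full(n, 1.0),               # radians
        np.full(n, problem.hw.smax),   # T/m/s
    ])
    scale = np.maximum(np.abs(x0), block_scale)
    for i, idx in enumerate(indices):
        h = rel_step * scale[idx]
        xp = x0.copy()
        xp[idx] += h
        xm = x0.copy()
        xm[idx] -= h
        jp = cost(ControlVector.unpack(xp, x.grid), problem, pen).total
        jm = cost(ControlVector.unpack(xm, x.grid), problem, pen).total
        out[i] = (jp - jm) / (2.0 * h)
    return out
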