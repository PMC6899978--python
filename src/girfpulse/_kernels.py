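"""Compiled inner loops for the spin-domain forward and adjoint sweeps.

The numba-jitted kernels mirror the vectorized numpy implementations in
:mod:`bloch` and :mod:`adjoint` operation for operation; the numpy paths
remain as fallback when numba is unavailable.  Keep the two in sync.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def forward_states(b1, g, z, tau, gamma, off_w, b1_scale):
    """State history of the hard-pulse spin-domain recursion.

    Returns (a_hist, b_hist) with shape (Nt, Nz); row 0 is the initial
    state (1, 0).
    """
    n = b1.size
    nz = z.size
    k = gamma * tau
    a_hist = np.empty((n + 1, nz), np.complex128)
    b_hist = np.empty((n + 1, nz), np.complex128)
    for iz in range(nz):
        a_hist[0, iz] = 1.0 + 0.0j
        b_hist[0, iz] = 0.0 + 0.0j
    for m in range(n):
        b1m = b1[m] * b1_scale
        r2 = b1m.real * b1m.real + b1m.imag * b1m.imag
        for iz in range(nz):
            w = z[iz] * g[m] + off_w
            phi = -k * np.sqrt(r2 + w * w)
            half = 0.5 * phi
            if abs(phi) < 1e-8:
                sinc_half = 0.5 - phi * phi / 48.0
            else:
                sinc_half = np.sin(half) / phi
            alpha = np.cos(half) + 1j * k * w * sinc_half
            beta = 1j * k * b1m * sinc_half
            ap = a_hist[m, iz]
            bp = b_hist[m, iz]
            a_hist[m + 1, iz] = alpha * ap - np.conj(beta) * bp
            b_hist[m + 1, iz] = beta * ap + np.conj(alpha) * bp
    return a_hist, b_hist


@njit(cache=False)
def reverse_sweep(r, theta, g_real, z, tau, gamma, a_hist, b_hist,
                  g_b_seed):
    """Adjoint sweep accumulating dJ/dr, dJ/dtheta, dJ/d(realized grad)."""
    n = r.size
    nz = z.size
    k = gamma * tau
    djdr = np.zeros(n)
    djdtheta = np.zeros(n)
    djdgt = np.zeros(n)
    g_a = np.zeros(nz, np.complex128)
    g_b = g_b_seed.copy()
    tiny = 1e-300
    for m in range(n - 1, -1, -1):
        rm = r[m]
        eitheta = np.cos(theta[m]) + 1j * np.sin(theta[m])
        b1m = rm * eitheta
        acc_r = 0.0
        acc_t = 0.0
        acc_g = 0.0
        for iz in range(nz):
            w = z[iz] * g_real[m]
            q = np.sqrt(rm * rm + w * w)
            phi = -k * q
            half = 0.5 * phi
            if abs(phi) < 1e-4:
                psi = 0.5 - phi * phi / 48.0 + phi ** 4 / 3840.0
                dpsi = -phi / 24.0 + phi ** 3 / 960.0
                cos_half = np.cos(half)
                sin_half = np.sin(half)
            else:
                cos_half = np.cos(half)
                sin_half = np.sin(half)
                psi = sin_half / phi
                dpsi = cos_half / (2.0 * phi) - sin_half / (phi * phi)
            alpha = cos_half + 1j * k * w * psi
            beta = 1j * k * b1m * psi
            q_safe = q if q > tiny else tiny
            dphi_dr = -k * rm / q_safe
            dphi_dw = -k * w / q_safe
            dalpha_dphi = -0.5 * sin_half + 1j * k * w * dpsi
            dbeta_dphi = 1j * k * b1m * dpsi
            dalpha_dr = dalpha_dphi * dphi_dr
            dbeta_dr = 1j * k * eitheta * psi + dbeta_dphi * dphi_dr
            dalpha_dg = z[iz] * (1j * k * psi + dalpha_dphi * dphi_dw)
            dbeta_dg = z[iz] * dbeta_dphi * dphi_dw
            dbeta_dth = 1j * beta

            ap = a_hist[m, iz]
            bp = b_hist[m, iz]
            ga_c = np.conj(g_a[iz])
            gb_c = np.conj(g_b[iz])
            acc_r += (ga_c * (dalpha_dr * ap - np.conj(dbeta_dr) * bp)
                      + gb_c * (dbeta_dr * ap + np.conj(dalpha_dr) * bp)).real
            acc_t += (ga_c * (-np.conj(dbeta_dth) * bp)
                      + gb_c * (dbeta_dth * ap)).real
            acc_g += (ga_c * (dalpha_dg * ap - np.conj(dbeta_dg) * bp)
                      + gb_c * (dbeta_dg * ap + np.conj(dalpha_dg) * bp)).real

            ga_new = np.conj(alpha) * g_a[iz] + np.conj(beta) * g_b[iz]
            g_b[iz] = -beta * g_a[iz] + alpha * g_b[iz]
            g_a[iz] = ga_new
        djdr[m] = acc_r
        djdtheta[m] = acc_t
        djdgt[m] = acc_g
    return djdr, djdtheta, djdgt
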