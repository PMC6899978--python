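"""Shinnar-Le Roux design of the PINS sub-pulse envelope.

The hard-pulse spin-domain recursion maps an RF sample train to a pair of
polynomials (A, B) in the per-period precession variable; selective pulse
design then reduces to FIR filter design for the beta polynomial followed
by the exact inverse recursion.  For a PINS pulse the hard-pulse model is
not an approximation: RF and gradient are never on simultaneously, so the
sampled-envelope flips and the inter-pulse gradient blips realize the
polynomial model exactly, with the profile periodic in the blip rotation
angle.

Conventions: real RF samples correspond to purely imaginary beta
coefficients (beta = i sin(flip/2) for a zero-phase hard pulse).  For the
crushed spin-echo (refocusing) case the beta passband target is 1 (full
inversion); passband overshoot beyond 1 is unrealizable for a unitary
rotation and is clipped by a small floor in the spectral factorization.
This convention was validated against independently published PINS
refocusing pulse durations (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

#: Floor applied to 1 - |B|^2 in the minimum-phase factorization.  With a
#: passband designed at full inversion, |B| grazes (and after least-squares
#: ripple, slightly exceeds) 1; the floor keeps the factorization defined
#: while committing the design to near-complete inversion there.
SPECTRAL_FLOOR = 1e-12


def dinf(d1: float, d2: float) -> float:
    """Parks-McClellan D-infinity estimate of the time-bandwidth cost of a
    transition for given passband/stopband ripples."""
    a = (5.309e-3, 7.114e-2, -4.761e-1, -2.66e-3, -5.941e-1, -4.278e-1)
    l1, l2 = np.log10(d1), np.log10(d2)
    return ((a[0] * l1 ** 2 + a[1] * l1 + a[2]) * l2
            + (a[3] * l1 ** 2 + a[4] * l1 + a[5]))


def fractional_transition_width(tbwp: float, d1: float, d2: float,
                                clamp: float = 0.9) -> float:
    """Transition half-width as a fraction of the slice half-width.

    ``dinf/tbwp`` in the usual filter-design scaling; clamped below
    ``clamp`` so that low time-bandwidth products (where the ripple spec
    is not strictly attainable) still leave a nonempty passband.
    """
    return min(dinf(d1, d2) / tbwp, clamp)


def firls_linear_phase(numtaps: int, bands, desired, weight,
                       ngrid: int = 4096) -> np.ndarray:
    """Linear-phase FIR design by weighted least squares on a dense grid.

    Supports even tap counts (type II) as well as odd (type I); scipy's
    least-squares designer is odd-only, and PINS sub-pulse counts are
    typically even.  ``bands`` are edge pairs in normalized frequency
    (Nyquist = 1) with piecewise-constant ``desired`` and ``weight``.
    """
    if numtaps < 2:
        raise ValueError("need at least 2 taps")
    half = numtaps // 2
    odd = numtaps % 2 == 1
    kappa = 0.0 if odd else 0.5
    ncoef = half + 1 if odd else half
    w = np.linspace(0.0, np.pi, ngrid)
    target = np.zeros(ngrid)
    wgt = np.zeros(ngrid)
    for i in range(0, len(bands), 2):
        m = (w >= bands[i] * np.pi) & (w <= bands[i + 1] * np.pi)
        target[m] = desired[i // 2]
        wgt[m] = weight[i // 2]
    k = np.arange(ncoef)
    basis = np.cos(np.outer(w, k + kappa))
    bw = basis * wgt[:, None]
    coef = np.linalg.lstsq(bw.T @ basis, bw.T @ target, rcond=None)[0]
    h = np.zeros(numtaps)
    if odd:
        h[half] = coef[0]
        h[half + 1:] = coef[1:] / 2
        h[:half] = coef[:0:-1] / 2
    else:
        h[half:] = coef / 2
        h[:half] = coef[::-1] / 2
    return h


def minimum_phase_alpha(bpoly: np.ndarray,
                        floor: float = SPECTRAL_FLOOR) -> np.ndarray:
    """Minimum-phase alpha polynomial with |A|^2 = 1 - |B|^2 on the unit
    circle, via cepstral spectral factorization."""
    n = len(bpoly)
    nfft = 1 << int(np.ceil(np.log2(max(n * 64, 256))))
    bw = fft(np.asarray(bpoly, dtype=complex), nfft)
    mag2 = np.maximum(1.0 - np.abs(bw) ** 2, floor)
    cep = ifft(np.log(mag2))
    lifter = np.zeros(nfft)
    lifter[0] = 1.0
    lifter[1:nfft // 2] = 2.0
    lifter[nfft // 2] = 1.0
    aw = np.exp(fft(lifter * cep) / 2.0)
    return np.asarray(ifft(aw)[:n])


def inverse_recursion(apoly: np.ndarray, bpoly: np.ndarray):
    """Exact inverse of the hard-pulse polynomial recursion.

    Returns per-sample rotation angles (rad, >= 0) and RF phases (rad).
    ``apoly`` holds coefficients of z^0..z^-(n-1), ``bpoly`` of
    z^-1..z^-n (the per-period precession applied after each hard pulse).
    """
    a = np.asarray(apoly, dtype=complex).copy()
    b = np.asarray(bpoly, dtype=complex).copy()
    if a.shape != b.shape:
        raise ValueError("polynomials must have equal length")
    n = len(b)
    flips = np.zeros(n)
    phases = np.zeros(n)
    for j in range(n - 1, -1, -1):
        rho = b[0] / a[0]
        theta = 2.0 * np.arctan(np.abs(rho))
        phi = float(np.angle(-1j * rho)) if np.abs(rho) > 0 else 0.0
        flips[j] = theta
        phases[j] = phi
        al = np.cos(theta / 2.0)
        be = 1j * np.exp(1j * phi) * np.sin(theta / 2.0)
        # undo the rotation; the precession z^-1 on B shifts indices down
        a_prev = np.conj(al) * a + np.conj(be) * b
        b_prev = -be * a + al * b
        if j >= 1:
            a = a_prev[:j]
            b = b_prev[1:j + 1]
        else:
            a, b = a_prev[:1], b_prev[:1]
    return flips, phases


def forward_recursion(flips: np.ndarray, phases: np.ndarray):
    """Hard-pulse polynomial recursion (the forward map inverted above)."""
    flips = np.asarray(flips, dtype=float)
    phases = np.asarray(phases, dtype=float)
    a = np.array([1.0 + 0j])
    b = np.zeros(0, dtype=complex)
    for j in range(len(flips)):
        al = np.cos(flips[j] / 2.0)
        be = 1j * np.exp(1j * phases[j]) * np.sin(flips[j] / 2.0)
        la = len(a)
        a_new = np.zeros(la + 1, dtype=complex)
        a_new[:la] = al * a
        a_new[1:1 + len(b)] += -np.conj(be) * b
        b_new = np.zeros(la + 1, dtype=complex)
        b_new[:la] = be * a
        b_new[1:1 + len(b)] += np.conj(al) * b
        a = a_new[:j + 1]
        b = b_new[:j + 1]
    return a, b


def beta_response(bpoly: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Evaluate B(e^{i omega}); omega is the per-period precession angle."""
    k = np.arange(1, len(bpoly) + 1)
    return np.exp(-1j * np.outer(np.asarray(omega, float), k)) @ bpoly


@dataclass
class SLRDesign:
    """A designed sub-pulse envelope: signed flip angles per hard pulse."""

    flips: np.ndarray          # signed rotation angles (rad)
    d1: float                  # passband ripple of the beta prototype
    d2: float                  # stopband ripple of the beta prototype
    tbwp: float
    nominal_flip: float        # rad (pi for refocusing)
    transition_width: float    # fractional, relative to the slice half-width

    @property
    def n_samples(self) -> int:
        return self.flips.size

    @property
    def bpoly(self) -> np.ndarray:
        a, b = forward_recursion(np.abs(self.flips),
                                 np.where(self.flips < 0, np.pi, 0.0))
        return b


def design_slr_subpulse(tbwp: float, d1: float, d2: float, n_samples: int,
                        purpose: str = "refocusing") -> SLRDesign:
    """Design the PINS sub-pulse envelope for a crushed-SE refocusing slice.

    The beta prototype is a linear-phase least-squares FIR with band edges
    at (1 -+ w) * tbwp/2 frequency bins (w from the D-infinity estimate),
    passband target sin(flip/2); for refocusing the target is 1.  The flip
    angles follow from the exact inverse hard-pulse recursion with a
    minimum-phase alpha.
    """
    if tbwp < 1:
        raise ValueError("time-bandwidth product must be >= 1")
    if n_samples < 8 * tbwp:
        raise ValueError(
            f"n_samples={n_samples} too small for TBWP={tbwp}; "
            f"need >= {int(8 * tbwp)}")
    if purpose not in ("refocusing",):
        raise ValueError(f"unsupported purpose {purpose!r}")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("ripples must be positive")
    w = fractional_transition_width(tbwp, d1, d2)
    half_band = tbwp / 2.0 / (n_samples / 2.0)  # normalized (Nyquist=1)
    bands = [0.0, (1.0 - w) * half_band, (1.0 + w) * half_band, 1.0]
    if bands[1] <= 0 or bands[2] >= 1.0:
        raise ValueError("infeasible ripple/TBWP combination")
    h = firls_linear_phase(n_samples, bands, [1.0, 0.0], [1.0, d1 / d2])
    bpoly = 1j * h  # real RF <-> purely imaginary beta coefficients
    apoly = minimum_phase_alpha(bpoly)
    flips, phases = inverse_recursion(apoly, bpoly)
    signed = flips * np.where(np.cos(phases) < 0.0, -1.0, 1.0)
    return SLRDesign(signed, d1, d2, tbwp, np.pi, w)
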