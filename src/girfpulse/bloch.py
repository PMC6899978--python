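"""Spin-domain Bloch simulation (Cayley-Klein parameters).

Relaxation is neglected; each raster interval applies one SU(2) rotation
with parameters (alpha, beta) that depend on the RF sample, the realized
gradient sample and the spatial position.  The crushed spin-echo
refocusing profile is the squared beta product ``|b|^2`` with phase
``arg(b^2)``; low-tip excitation performance is read off as the flip angle
``asin(|2 a b*|)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import _kernels
from .constants import GAMMA_1H
from .waveforms import RFWaveform, TimeGrid


@dataclass(frozen=True)
class SpatialGrid:
    """Equidistant positions spanning [-FOV/2, FOV/2] along slice select."""

    fov: float
    nz: int

    def __post_init__(self) -> None:
        if self.fov <= 0 or self.nz < 1:
            raise ValueError("fov must be positive and nz >= 1")

    @property
    def delta(self) -> float:
        """Spatial resolution FOV / Nz in meters."""
        return self.fov / self.nz

    @property
    def z(self) -> np.ndarray:
        """Positions (m), cell-centered and symmetric about 0."""
        return (np.arange(self.nz) - (self.nz - 1) / 2) * self.delta


@dataclass
class SpinDomainProfile:
    """Cayley-Klein pair (a, b) per spatial position."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=complex)
        self.b = np.asarray(self.b, dtype=complex)
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have equal shape")

    @property
    def norm_error(self) -> float:
        """Max deviation of |a|^2 + |b|^2 from 1."""
        return float(np.max(np.abs(np.abs(self.a) ** 2
                                   + np.abs(self.b) ** 2 - 1.0)))


@dataclass(frozen=True)
class PerturbationGrid:
    """B1 scale factors and B0 offsets (Hz) for robustness sweeps."""

    b1_scales: tuple = (1.0,)
    b0_offsets_hz: tuple = (0.0,)

    @classmethod
    def default_sweep(cls) -> "PerturbationGrid":
        """75-125% B1 in 5% steps, +-200 Hz off-resonance in 25 Hz steps."""
        return cls(tuple(np.round(np.arange(0.75, 1.2501, 0.05), 4)),
                   tuple(np.arange(-200.0, 200.1, 25.0)))


def rotation_parameters(b1: complex | np.ndarray, w: np.ndarray, tau: float):
    """Per-interval Cayley-Klein coefficients.

    ``w`` is the local z-rotation rate term ``z * G~s + 2 pi df / gamma``
    (T-equivalent), ``b1`` the complex RF sample (T).  The rotation angle
    is ``phi = -gamma tau sqrt(|b1|^2 + w^2)``; the degenerate phi -> 0
    limit gives (alpha, beta) = (1, 0).
    """
    k = GAMMA_1H * tau
    r2 = np.abs(b1) ** 2
    phi = -k * np.sqrt(r2 + w * w)  # -gamma tau sqrt(|b1|^2 + w^2)
    half = 0.5 * phi
    small = np.abs(phi) < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc_half = np.where(small, 0.5 - phi * phi / 48.0,
                             np.sin(half) / np.where(phi == 0.0, 1.0, phi))
    alpha = np.cos(half) + 1j * k * w * sinc_half
    beta = 1j * k * b1 * sinc_half
    return alpha, beta


def simulate(rf, grad_realized, grid: TimeGrid, space: SpatialGrid,
             b1_scale: float = 1.0, b0_offset_hz: float = 0.0,
             return_states: bool = False):
    """Propagate (a, b) from (1, 0) through all raster intervals.

    ``rf`` may be an :class:`RFWaveform` or a complex B1 array (T);
    ``grad_realized`` is the realized gradient sequence (T/m).  With
    ``return_states`` the full state history (Nt, Nz) is returned for
    adjoint computations.
    """
    b1 = rf.b1 if isinstance(rf, RFWaveform) else np.asarray(rf, dtype=complex)
    gs = np.asarray(grad_realized, dtype=float)
    n = grid.n_intervals
    if b1.shape != (n,) or gs.shape != (n,):
        raise ValueError("rf/gradient length must equal Nt-1")
    if not (np.all(np.isfinite(b1)) and np.all(np.isfinite(gs))):
        raise ValueError("non-finite waveform samples")
    z = space.z
    nz = z.size
    off = 2.0 * np.pi * b0_offset_hz / GAMMA_1H  # constant T-equivalent
    if _kernels.HAVE_NUMBA:
        a_hist, b_hist = _kernels.forward_states(
            np.ascontiguousarray(b1), np.ascontiguousarray(gs),
            np.ascontiguousarray(z), grid.tau, GAMMA_1H, off,
            complex(b1_scale))
        prof = SpinDomainProfile(a_hist[-1], b_hist[-1])
        if return_states:
            return prof, a_hist, b_hist
        return prof
    a = np.ones(nz, dtype=complex)
    b = np.zeros(nz, dtype=complex)
    if return_states:
        a_hist = np.empty((n + 1, nz), dtype=complex)
        b_hist = np.empty((n + 1, nz), dtype=complex)
        a_hist[0] = a
        b_hist[0] = b
    for m in range(n):
        w = z * gs[m] + off
        alpha, beta = rotation_parameters(b1[m] * b1_scale, w, grid.tau)
        a, b = alpha * a - np.conj(beta) * b, beta * a + np.conj(alpha) * b
        if return_states:
            a_hist[m + 1] = a
            b_hist[m + 1] = b
    if return_states:
        return SpinDomainProfile(a, b), a_hist, b_hist
    return SpinDomainProfile(a, b)


def refocusing_profile(p: SpinDomainProfile):
    """Crushed spin-echo observable: magnitude |b|^2 and phase arg(b^2)."""
    return np.abs(p.b) ** 2, np.angle(p.b ** 2)


def excitation_flip_angle(p: SpinDomainProfile) -> np.ndarray:
    """Flip angle asin(|2 a b*|) per position (rad)."""
    return np.arcsin(np.clip(np.abs(2.0 * p.a * np.conj(p.b)), 0.0, 1.0))


def robustness_sweep(rf, grad_realized, grid: TimeGrid, space: SpatialGrid,
                     perturb: PerturbationGrid):
    """Refocusing magnitude/phase over a (B1 scale, B0 offset) grid.

    Returns two arrays of shape (len(b1_scales), len(b0_offsets), Nz).
    """
    nb1 = len(perturb.b1_scales)
    nb0 = len(perturb.b0_offsets_hz)
    mag = np.empty((nb1, nb0, space.nz))
    phase = np.empty((nb1, nb0, space.nz))
    for (i, s), (j, df) in product(enumerate(perturb.b1_scales),
                                   enumerate(perturb.b0_offsets_hz)):
        prof = simulate(rf, grad_realized, grid, space, s, df)
        mag[i, j], phase[i, j] = refocusing_profile(prof)
    return mag, phase


def compose(first: SpinDomainProfile, second: SpinDomainProfile) -> SpinDomainProfile:
    """Compose two spin-domain propagators (second applied after first)."""
    a = second.a * first.a - np.conj(second.b) * first.b
    b = second.b * first.a + np.conj(second.a) * first.b
    return SpinDomainProfile(a, b)
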