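"""PINS initialization: hard RF sub-pulses interleaved with gradient blips.

A PINS pulse plays the SLR sub-pulse envelope as N hard pulses with the
gradient off, separated by N-1 minimum-time gradient blips whose zeroth
moment advances the periodic slice pattern by one cycle per slice spacing.
RF power is independent of the number of slices, which makes PINS a robust,
always-feasible starting point for the time-optimal design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_1H, GAMMA_BAR_1H
from .slr import SLRDesign, design_slr_subpulse, fractional_transition_width
from .waveforms import (GradientWaveform, HardwareBounds, RFWaveform,
                        TimeGrid, differentiate_gradient)


@dataclass
class SliceSpec:
    """Multi-slice geometry and the derived spatial domain partition.

    Slices of thickness ``thk`` are uniformly spaced by ``fov / mb`` across
    the design field of view.  Each slice edge carries a transition band of
    half-width ``transition * thk / 2`` on both sides, belonging to neither
    the in-slice nor the out-of-slice set.
    """

    mb: int
    thk: float
    fov: float
    tbwp: float
    transition: float  # fractional transition width of the SLR prototype

    def __post_init__(self) -> None:
        if self.mb < 1:
            raise ValueError("need at least one slice")
        if self.mb * self.thk >= self.fov:
            raise ValueError("slices do not fit in the field of view")

    @property
    def spacing(self) -> float:
        return self.fov / self.mb

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.mb) - (self.mb - 1) / 2.0) * self.spacing

    @property
    def in_edge(self) -> float:
        """In-slice half-width (inner transition edge)."""
        return (1.0 - self.transition) * self.thk / 2.0

    @property
    def out_edge(self) -> float:
        """Out-of-slice inner boundary (outer transition edge)."""
        return (1.0 + self.transition) * self.thk / 2.0

    def domains(self, z: np.ndarray):
        """Index masks (in-slice, out-of-slice, per-slice in-slice list)."""
        z = np.asarray(z, dtype=float)
        if self.out_edge >= self.spacing / 2.0:
            raise ValueError("transition bands of neighboring slices overlap")
        dist = np.min(np.abs(z[:, None] - self.centers[None, :]), axis=1)
        in_mask = dist <= self.in_edge
        out_mask = dist >= self.out_edge
        per_slice = []
        for c in self.centers:
            mask = np.abs(z - c) <= self.in_edge
            if not np.any(mask):
                # coarse spatial grids: always constrain at least the
                # grid point nearest to the slice center
                mask = np.zeros(z.size, bool)
                mask[np.argmin(np.abs(z - c))] = True
            per_slice.append(mask)
        in_mask = in_mask | np.any(per_slice, axis=0)
        out_mask = out_mask & ~in_mask
        return in_mask, out_mask, per_slice


def build_slice_domains(mb: int, thk: float, fov: float, tbwp: float,
                        d1: float = 0.01 / 4, d2: float = 0.01 / 2,
                        transition: float | None = None) -> SliceSpec:
    """Slice specification with the transition width inherited from the
    SLR prototype (unless given explicitly)."""
    if transition is None:
        transition = fractional_transition_width(tbwp, d1, d2)
    return SliceSpec(mb, thk, fov, tbwp, transition)


def minimum_time_blip(area: float, bounds: HardwareBounds,
                      tau: float) -> np.ndarray:
    """Minimum-time triangular/trapezoidal gradient lobe of given zeroth
    moment (T s / m), piecewise constant on the raster.

    The continuous minimum-time lobe (ramps at the slew limit) is rounded
    up to whole raster intervals, sampled at interval midpoints and
    rescaled to the exact area, which keeps slew and amplitude within
    bounds.
    """
    if area <= 0:
        raise ValueError("blip area must be positive")
    n_tri = int(np.ceil(np.sqrt(area / (bounds.smax * tau ** 2))))
    if n_tri * bounds.smax * tau <= bounds.gmax:
        ramp = np.arange(1, n_tri + 1) - 0.5
        shape = np.concatenate([ramp, ramp[::-1]])
    else:
        n_ramp = int(np.ceil(bounds.gmax / (bounds.smax * tau)))
        n_flat = max(0, int(np.ceil(area / (tau * bounds.gmax) - n_ramp)))
        ramp = np.arange(1, n_ramp + 1) - 0.5
        shape = np.concatenate([ramp, np.full(n_flat, float(n_ramp)),
                                ramp[::-1]])
    g = shape * (area / (tau * shape.sum()))
    slew = np.diff(g, prepend=0.0, append=0.0) / tau
    if np.max(np.abs(slew)) > bounds.smax * (1 + 1e-9) or \
            g.max() > bounds.gmax * (1 + 1e-9):
        raise ValueError("required blip area unreachable under bounds")
    return g


def build_pins(mb: int, thk: float, fov: float, tbwp: float,
               bounds: HardwareBounds, tau: float,
               d1: float = 0.01 / 4, d2: float = 0.01 / 2,
               slr: SLRDesign | None = None):
    """Construct the PINS initial guess.

    Returns ``(rf, grad, grid, spec)``: a real-valued RF waveform, the
    blipped gradient, the time grid and the slice specification.  The
    number of sub-pulses is ``N = ceil(TBWP * spacing / THK)``; every
    sub-pulse is played at the common minimum duration allowed by the peak
    flip angle and the RF amplitude limit, rounded up to the raster; each
    blip is the minimum-time lobe whose moment advances the periodic
    pattern by one cycle across the slice spacing.
    """
    spec = build_slice_domains(mb, thk, fov, tbwp, d1, d2)
    spacing = spec.spacing
    n_sub = int(np.ceil(tbwp * spacing / thk))
    if slr is None:
        slr = design_slr_subpulse(tbwp, d1, d2, n_sub)
    elif slr.n_samples != n_sub:
        raise ValueError("supplied SLR design has wrong sample count")
    area = 1.0 / (GAMMA_BAR_1H * spacing)
    blip = minimum_time_blip(area, bounds, tau)
    flips = slr.flips
    if mb % 2 == 0:
        # even slice counts place slices at odd half-multiples of the
        # spacing; alternating sub-pulse signs shift the periodic pattern
        # by half a period without changing amplitudes or durations
        flips = flips * (-1.0) ** np.arange(n_sub)
    peak = np.abs(flips).max()
    d_sub = max(1, int(np.ceil(peak / (GAMMA_1H * bounds.rmax * tau))))
    amps = flips / (GAMMA_1H * d_sub * tau)  # signed real B1 (T)
    b1 = []
    gs = []
    zeros_rf = [0.0] * blip.size
    for j in range(n_sub):
        b1.extend([amps[j]] * d_sub)
        gs.extend([0.0] * d_sub)
        if j < n_sub - 1:
            b1.extend(zeros_rf)
            gs.extend(blip.tolist())
    b1 = np.asarray(b1)
    gs = np.asarray(gs)
    grid = TimeGrid(tau, b1.size + 1)
    rf = RFWaveform.from_signed_real(b1)
    grad = GradientWaveform(gs, differentiate_gradient(gs, grid))
    return rf, grad, grid, spec
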