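"""Penalized design objective, profile constraints and SAR tracking.

The cost is the pulse duration plus an RF-energy term plus even-power
(Lp) penalties of the normalized constraint residuals: demanded gradient
amplitude, out-of-slice and in-slice refocusing-magnitude errors, and
per-slice phase spread.  The exponent p is doubled during the optimization
so the penalties approach an L-infinity (max-violation) behavior; the
weights are re-balanced every 20 optimization steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import SpatialGrid, simulate, refocusing_profile
from .girf import FilterOperator, TransferFunction, filter_matrix
from .pins import SliceSpec
from .waveforms import (ControlVector, HardwareBounds, TimeGrid,
                        integrate_slew)


@dataclass(frozen=True)
class ProfileBounds:
    """Error bounds of the refocusing profile.

    ``e_in``/``e_out`` bound the in-slice and out-of-slice deviation of
    |b|^2 from 1 and 0; ``e_p`` bounds the in-slice deviation of the
    profile phase from its per-slice mean (rad).
    """

    e_in: float
    e_out: float
    e_p: float

    def __post_init__(self) -> None:
        if min(self.e_in, self.e_out, self.e_p) <= 0:
            raise ValueError("error bounds must be positive")
        if not (0 < self.e_p < np.pi):
            raise ValueError("phase bound must lie in (0, pi)")

    @property
    def es(self) -> float:
        """Scalar shorthand max(e_in, e_out)."""
        return max(self.e_in, self.e_out)

    @classmethod
    def uniform(cls, es: float, e_p: float = 0.025) -> "ProfileBounds":
        return cls(es, es, e_p)


@dataclass
class PenaltyState:
    """Penalty weights, the even exponent p, and the adaptation counter."""

    mu_rf: float = 1e-3
    mu_g: float = 1.0
    mu_out: float = 1.0
    mu_in: float = 1.0
    mu_p: float = 1.0
    p: int = 2
    adapt_every: int = 20
    p_max: int = 32
    iteration: int = 0

    def __post_init__(self) -> None:
        _check_exponent(self.p)
        if min(self.mu_rf, self.mu_g, self.mu_out, self.mu_in, self.mu_p) <= 0:
            raise ValueError("penalty weights must be positive")


def _check_exponent(p: int) -> None:
    if p < 2 or p % 2 != 0:
        raise ValueError(f"penalty exponent must be an even integer >= 2, got {p}")


@dataclass(frozen=True)
class SARConfig:
    """Global SAR estimate parameters: pulse rate (1/s), coil efficiency
    (W/kg/uT^2) and the safety limit (W/kg)."""

    f_p: float = 16.67
    coil_eff: float = 0.25
    sar_max: float = 3.2

    def __post_init__(self) -> None:
        if min(self.f_p, self.coil_eff, self.sar_max) <= 0:
            raise ValueError("SAR parameters must be positive")


@dataclass
class DesignProblem:
    """Everything the cost needs besides the controls."""

    spec: SliceSpec
    space: SpatialGrid
    hw: HardwareBounds
    bounds: ProfileBounds
    girf: TransferFunction | None = None
    sar: SARConfig = field(default_factory=SARConfig)
    real_valued: bool = True

    def filter_op(self, grid: TimeGrid) -> FilterOperator | None:
        if self.girf is None:
            return None
        return filter_matrix(self.girf, grid)

    def domains(self):
        return self.spec.domains(self.space.z)


def magnitude_violations(mag: np.ndarray, spec: SliceSpec,
                         bounds: ProfileBounds,
                         space: SpatialGrid) -> np.ndarray:
    """Signed bound residuals of |b|^2 per position (positive = violated).

    Out-of-slice: |b|^2 - e_out; in-slice: (1 - |b|^2) - e_in; transition
    bands contribute 0.
    """
    in_mask, out_mask, _ = spec.domains(space.z)
    v = np.zeros_like(mag)
    v[out_mask] = mag[out_mask] - bounds.e_out
    v[in_mask] = (1.0 - mag[in_mask]) - bounds.e_in
    return v


def slice_mean_phase(phase: np.ndarray, mask: np.ndarray) -> float:
    """Wrap-safe mean: argument of the mean in-slice unit phasor."""
    if not np.any(mask):
        raise ValueError("empty slice set")
    return float(np.angle(np.mean(np.exp(1j * phase[mask]))))


def wrap_angle(x: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * np.asarray(x)))


def phase_violations(phase: np.ndarray, spec: SliceSpec,
                     bounds: ProfileBounds, space: SpatialGrid):
    """Per-slice phase-spread residuals |wrap(phi - mean_l)| - e_p.

    Returns a list of per-slice residual arrays (positive = violated).
    """
    _, _, per_slice = spec.domains(space.z)
    out = []
    for mask in per_slice:
        mean = slice_mean_phase(phase, mask)
        dev = wrap_angle(phase[mask] - mean)
        out.append(np.abs(dev) - bounds.e_p)
    return out


def sar_estimate(rf, grid: TimeGrid, cfg: SARConfig) -> float:
    """Global SAR estimate: coil_eff * f_p * tau * sum(r_m^2), r in uT."""
    r = rf.r if hasattr(rf, "r") else np.asarray(rf)
    r_ut = r * 1e6
    return float(cfg.coil_eff * cfg.f_p * grid.tau * np.sum(r_ut ** 2))


@dataclass
class CostBreakdown:
    duration: float
    rf_energy: float
    grad_amplitude: float
    out_of_slice: float
    in_slice: float
    phase: float

    @property
    def total(self) -> float:
        return (self.duration + self.rf_energy + self.grad_amplitude
                + self.out_of_slice + self.in_slice + self.phase)

    def as_dict(self) -> dict:
        return {
            "duration": self.duration,
            "rf_energy": self.rf_energy,
            "grad_amplitude": self.grad_amplitude,
            "out_of_slice": self.out_of_slice,
            "in_slice": self.in_slice,
            "phase": self.phase,
            "total": self.total,
        }


def profile_from_controls(x: ControlVector, problem: DesignProblem,
                          return_states: bool = False):
    """Forward model: slew -> Gs -> realized gradient -> spin domain."""
    grad = integrate_slew(x.s, x.grid)
    op = problem.filter_op(x.grid)
    g_real = grad.gs if op is None else op.apply(grad.gs)
    b1 = x.r * np.exp(1j * x.theta)
    result = simulate(b1, g_real, x.grid, problem.space,
                      return_states=return_states)
    return result, grad, g_real


def cost(x: ControlVector, problem: DesignProblem,
         pen: PenaltyState) -> CostBreakdown:
    """Evaluate the penalized cost with its term breakdown."""
    _check_exponent(pen.p)
    prof, grad, _ = profile_from_controls(x, problem)
    mag, phase = refocusing_profile(prof)
    return _cost_terms(x, grad.gs, mag, phase, problem, pen)


def _cost_terms(x: ControlVector, gs: np.ndarray, mag: np.ndarray,
                phase: np.ndarray, problem: DesignProblem,
                pen: PenaltyState) -> CostBreakdown:
    tau = x.grid.tau
    p = pen.p
    delta = problem.space.delta
    in_mask, out_mask, per_slice = problem.domains()
    t_term = x.grid.duration
    rf_term = tau * pen.mu_rf / 2.0 * float(np.sum(x.r ** 2))
    g_term = tau * pen.mu_g / p * float(np.sum((gs / problem.hw.gmax) ** p))
    out_term = delta * pen.mu_out / (2.0 * p) * float(
        np.sum((mag[out_mask] / problem.bounds.e_out) ** p))
    in_term = delta * pen.mu_in / (2.0 * p) * float(
        np.sum(((1.0 - mag[in_mask]) / problem.bounds.e_in) ** p))
    ph_term = 0.0
    for mask in per_slice:
        mean = slice_mean_phase(phase, mask)
        dev = wrap_angle(phase[mask] - mean)
        ph_term += float(np.sum((dev / problem.bounds.e_p) ** p))
    ph_term *= delta * pen.mu_p / p
    return CostBreakdown(t_term, rf_term, g_term, out_term, in_term, ph_term)


def max_violations(x: ControlVector, problem: DesignProblem):
    """Maximal signed residuals of all state constraints for feasibility
    checks and weight adaptation.

    Returns a dict with keys 'magnitude', 'phase', 'gradient' (positive =
    violated) evaluated with the design transfer function in the loop.
    """
    prof, grad, _ = profile_from_controls(x, problem)
    mag, phase = refocusing_profile(prof)
    in_mask, out_mask, _ = problem.domains()
    pv = phase_violations(phase, problem.spec, problem.bounds, problem.space)
    gv = np.abs(grad.gs) - problem.hw.gmax
    v_out = float(np.max(mag[out_mask] - problem.bounds.e_out)) \
        if np.any(out_mask) else -problem.bounds.e_out
    v_in = float(np.max((1.0 - mag[in_mask]) - problem.bounds.e_in)) \
        if np.any(in_mask) else -problem.bounds.e_in
    return {
        "magnitude_out": v_out,
        "magnitude_in": v_in,
        "magnitude": max(v_out, v_in),
        "phase": float(max(np.max(v) for v in pv)) if pv else -problem.bounds.e_p,
        "gradient": float(np.max(gv)) if gv.size else 0.0,
    }


def adapt_weights(pen: PenaltyState, violations: dict, bounds: ProfileBounds,
                  sar_now: float | None = None,
                  sar_cfg: SARConfig | None = None) -> PenaltyState:
    """Re-balance the penalty weights from the current residuals.

    A violated constraint group doubles its weight; a comfortably
    satisfied one (residual below -0.1x its bound) relaxes by 1/1.25.
    Weights are clamped to [1e-6, 1e9].  If the SAR estimate exceeds its
    limit, the RF-energy weight doubles.
    """
    def update(mu, viol, bound):
        if viol > 0:
            mu = mu * 2.0
        elif viol < -0.1 * bound:
            mu = mu / 1.25
        return float(np.clip(mu, 1e-6, 1e9))

    v_out = violations.get("magnitude_out", violations.get("magnitude", 0.0))
    v_in = violations.get("magnitude_in", violations.get("magnitude", 0.0))
    new = replace(
        pen,
        mu_out=update(pen.mu_out, v_out, bounds.e_out),
        mu_in=update(pen.mu_in, v_in, bounds.e_in),
        mu_p=update(pen.mu_p, violations["phase"], bounds.e_p),
        mu_g=update(pen.mu_g, violations["gradient"], 1e-3),
    )
    if sar_now is not None and sar_cfg is not None and sar_now > sar_cfg.sar_max:
        new = replace(new, mu_rf=float(np.clip(new.mu_rf * 2.0, 1e-6, 1e9)))
    return new


def continue_p(pen: PenaltyState) -> PenaltyState:
    """Double the penalty exponent (saturating at p_max)."""
    return replace(pen, p=min(2 * pen.p, pen.p_max))
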