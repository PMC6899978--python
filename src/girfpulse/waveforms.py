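"""Waveform containers on a uniform time raster, and the control-space maps.

The controls of the pulse-design problem are the RF amplitude ``r`` (T),
the RF phase ``theta`` (rad) and the gradient slew rate ``s`` (T/m/s),
each piecewise constant over the ``Nt - 1`` raster intervals of a
:class:`TimeGrid`.  The slice-select gradient ``Gs`` is a *state*: the
cumulative integral of the slew starting from 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time raster with ``Nt`` grid points and step ``tau`` (s)."""

    tau: float
    nt: int

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"raster step must be positive, got {self.tau}")
        if self.nt < 2:
            raise ValueError(f"need at least 2 grid points, got {self.nt}")

    @property
    def duration(self) -> float:
        """Total duration T = (Nt - 1) * tau in seconds."""
        return (self.nt - 1) * self.tau

    @property
    def n_intervals(self) -> int:
        return self.nt - 1

    @property
    def t(self) -> np.ndarray:
        """Grid-point times in seconds."""
        return np.arange(self.nt) * self.tau

    def with_intervals(self, n_intervals: int) -> "TimeGrid":
        return TimeGrid(self.tau, n_intervals + 1)


@dataclass
class RFWaveform:
    """Piecewise-constant RF pulse in polar coordinates.

    ``r`` is the non-negative amplitude in tesla per interval, ``theta``
    the phase in rad.  ``real_valued`` marks pulses whose phase is
    restricted to {0, pi}, i.e. signed real B1.
    """

    r: np.ndarray
    theta: np.ndarray
    real_valued: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.r.shape != self.theta.shape or self.r.ndim != 1:
            raise ValueError("r and theta must be 1-D arrays of equal length")

    @property
    def b1(self) -> np.ndarray:
        """Complex B1 samples r * exp(i theta) in tesla."""
        return self.r * np.exp(1j * self.theta)

    @property
    def n_intervals(self) -> int:
        return self.r.size

    @classmethod
    def from_signed_real(cls, b1_real: np.ndarray) -> "RFWaveform":
        """Build a real-valued pulse from signed real B1 samples (T)."""
        b1_real = np.asarray(b1_real, dtype=float)
        theta = np.where(b1_real < 0, np.pi, 0.0)
        return cls(np.abs(b1_real), theta, real_valued=True)


@dataclass
class GradientWaveform:
    """Demanded slice-select gradient (T/m) and its slew (T/m/s).

    The two representations are linked through the raster step:
    ``Gs[0] = tau * s[0]`` and ``Gs[m] - Gs[m-1] = tau * s[m]``, with an
    implicit gradient of 0 before the first interval.
    """

    gs: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.gs = np.asarray(self.gs, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.gs.shape != self.s.shape or self.gs.ndim != 1:
            raise ValueError("gs and s must be 1-D arrays of equal length")

    @property
    def n_intervals(self) -> int:
        return self.gs.size


@dataclass(frozen=True)
class HardwareBounds:
    """Hard amplitude limits: peak RF (T), peak gradient (T/m), slew (T/m/s)."""

    rmax: float
    gmax: float
    smax: float

    def __post_init__(self) -> None:
        if min(self.rmax, self.gmax, self.smax) <= 0:
            raise ValueError("hardware bounds must be strictly positive")


@dataclass
class ControlVector:
    """The optimization variables (r, theta, s) tied to a time grid."""

    r: np.ndarray
    theta: np.ndarray
    s: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        n = self.grid.n_intervals
        for name in ("r", "theta", "s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} must have length Nt-1 = {n}, got {arr.shape}"
                )
            setattr(self, name, arr)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.r, self.theta, self.s])

    @classmethod
    def unpack(cls, x: np.ndarray, grid: TimeGrid) -> "ControlVector":
        n = grid.n_intervals
        x = np.asarray(x, dtype=float)
        if x.size != 3 * n:
            raise ValueError(f"expected {3 * n} entries, got {x.size}")
        return cls(x[:n].copy(), x[n:2 * n].copy(), x[2 * n:].copy(), grid)

    def copy(self) -> "ControlVector":
        return ControlVector(self.r.copy(), self.theta.copy(), self.s.copy(),
                             self.grid)


def integrate_slew(s: np.ndarray, grid: TimeGrid) -> GradientWaveform:
    """Integrate a slew sequence into the demanded gradient.

    ``Gs[m] = tau * sum_{j<=m} s[j]`` with the gradient starting from 0.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (grid.n_intervals,):
        raise ValueError(
            f"slew length {s.shape} does not match grid intervals "
            f"{grid.n_intervals}"
        )
    gs = grid.tau * np.cumsum(s)
    return GradientWaveform(gs, s.copy())


def differentiate_gradient(gs: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Recover the slew sequence from a gradient sequence (inverse of
    :func:`integrate_slew`, exact up to floating-point rounding)."""
    gs = np.asarray(gs, dtype=float)
    if gs.shape != (grid.n_intervals,):
        raise ValueError("gradient length does not match grid")
    return np.diff(gs, prepend=0.0) / grid.tau


def project_controls(x: ControlVector, bounds: HardwareBounds) -> ControlVector:
    """Componentwise projection of the controls onto the hardware box.

    r into [0, rmax], s into [-smax, smax], theta into [-pi, pi].  The
    projection is idempotent and non-expansive.
    """
    return ControlVector(
        np.clip(x.r, 0.0, bounds.rmax),
        np.clip(x.theta, -np.pi, np.pi),
        np.clip(x.s, -bounds.smax, bounds.smax),
        x.grid,
    )


def resample_controls(x: ControlVector, grid_new: TimeGrid,
                      bounds: HardwareBounds | None = None,
                      real_valued: bool = False) -> ControlVector:
    """Linearly interpolate controls in normalized time onto a new grid.

    The raster step is preserved; the pulse duration changes through the
    number of grid points.  For real-valued pulses (phase restricted to
    {0, pi}) the *signed* amplitude is interpolated, so sign alternation
    patterns survive the regridding; interpolating amplitude and phase
    separately would scramble them.  If ``bounds`` is given the result is
    projected onto the hardware box afterwards.
    """
    if abs(grid_new.tau - x.grid.tau) > 1e-15 * x.grid.tau:
        raise ValueError("resampling must preserve the raster step")
    n_old, n_new = x.grid.n_intervals, grid_new.n_intervals
    if n_new == n_old:
        out = x.copy()
    else:
        # interval midpoints in normalized time
        t_old = (np.arange(n_old) + 0.5) / n_old
        t_new = (np.arange(n_new) + 0.5) / n_new
        if real_valued:
            signed = np.interp(t_new, t_old, x.r * np.cos(x.theta))
            r_new = np.abs(signed)
            theta_new = np.where(signed < 0, np.pi, 0.0)
        else:
            r_new = np.interp(t_new, t_old, x.r)
            theta_new = np.interp(t_new, t_old, x.theta)
        out = ControlVector(
            r_new,
            theta_new,
            np.interp(t_new, t_old, x.s),
            grid_new,
        )
    if bounds is not None:
        out = project_controls(out, bounds)
    return out


def satisfies_bounds(x: ControlVector, bounds: HardwareBounds) -> bool:
    """Exact (no-tolerance) check of the hard control bounds."""
    return bool(
        np.all(x.r >= 0.0) and np.all(x.r <= bounds.rmax)
        and np.all(np.abs(x.s) <= bounds.smax)
        and np.all(np.abs(x.theta) <= np.pi)
    )


# ---------------------------------------------------------------------------
# plain-text interchange format
# ---------------------------------------------------------------------------

def save_waveforms(path, rf: RFWaveform, grad: GradientWaveform,
                   grid: TimeGrid) -> None:
    """Write RF and gradient to a columnar CSV.

    Columns: time_s, rf_real_uT, rf_imag_uT, grad_mT_per_m.  The header
    records tau and Nt so the file round-trips bit-exactly (float values
    are written with repr-level precision).
    """
    b1 = rf.b1
    gs = grad.gs
    t = np.arange(grid.n_intervals) * grid.tau
    lines = [
        f"# tau_s={float(grid.tau)!r} nt={grid.nt} "
        f"real_valued={int(rf.real_valued)}",
        # display columns in customary units; hex columns carry the exact
        # SI values so that save -> load round-trips bit for bit
        "time_s,rf_real_uT,rf_imag_uT,grad_mT_per_m,"
        "rf_real_T_hex,rf_imag_T_hex,grad_T_m_hex",
    ]
    for m in range(grid.n_intervals):
        lines.append(
            f"{float(t[m])!r},{float(b1.real[m] * 1e6)!r},"
            f"{float(b1.imag[m] * 1e6)!r},{float(gs[m] * 1e3)!r},"
            f"{float(b1.real[m]).hex()},{float(b1.imag[m]).hex()},"
            f"{float(gs[m]).hex()}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def load_waveforms(path) -> tuple[RFWaveform, GradientWaveform, TimeGrid]:
    """Read waveforms written by :func:`save_waveforms`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("#"):
        raise ValueError("missing metadata header line")
    meta = dict(item.split("=") for item in header[1:].split())
    tau = float(meta["tau_s"])
    nt = int(meta["nt"])
    real_valued = bool(int(meta.get("real_valued", "0")))
    rows = [ln.split(",") for ln in lines[2:]]
    if len(rows) != nt - 1:
        raise ValueError("row count does not match header Nt")
    grid = TimeGrid(tau, nt)
    if len(rows[0]) >= 7:  # exact SI columns present
        b1 = np.array([float.fromhex(r[4]) + 1j * float.fromhex(r[5])
                       for r in rows])
        gs = np.array([float.fromhex(r[6]) for r in rows])
    else:
        b1 = np.array([float(r[1]) + 1j * float(r[2]) for r in rows]) * 1e-6
        gs = np.array([float(r[3]) for r in rows]) * 1e-3
    if real_valued:
        rf = RFWaveform.from_signed_real(b1.real)
    else:
        rf = RFWaveform(np.abs(b1), np.angle(b1))
    grad = GradientWaveform(gs, differentiate_gradient(gs, grid))
    return rf, grad, grid


def rampdown_trapezoid(g_final: float, bounds: HardwareBounds,
                       tau: float) -> np.ndarray:
    """Minimum-time ramp bringing a gradient value back to zero.

    Exported for sequence assembly only; the ramp lives outside the
    optimized window and is not part of the designed duration.
    """
    n = int(np.ceil(abs(g_final) / (bounds.smax * tau)))
    if n == 0:
        return np.zeros(0)
    return g_final * np.arange(n - 1, -1, -1) / n
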