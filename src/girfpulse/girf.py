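"""Linear time-invariant gradient-system model.

The gradient chain (amplifier, coil, eddy currents, mechanical modes) is
characterized by its impulse response; the demanded slice-select gradient
``Gs`` maps to the realized gradient ``G~s`` by convolution with that
response, or equivalently by multiplication with the transfer function
``H(f)`` in the frequency domain.  Measured transfer functions of whole-body
gradient systems are low-pass with an additional phase delay; both effects
shift and smooth rapidly varying gradient shapes.

The module exposes the filtering both as an FFT-based operator
(:func:`apply_girf`) and as an explicit dense matrix with its transpose
(:func:`filter_matrix`) for use in adjoint/chain-rule computations.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

from .waveforms import GradientWaveform, TimeGrid

logger = logging.getLogger(__name__)

#: Distinguished return of :func:`cutoff_frequency` when the magnitude
#: response never falls to half its DC value inside the tabulated band.
NO_CUTOFF = None


@dataclass(frozen=True)
class TransferFunction:
    """Tabulated complex frequency response of one gradient axis.

    ``f`` is a uniformly spaced two-sided frequency axis in Hz and ``h``
    the complex response.  Outside the tabulated support the response is
    taken to be zero (measured gradient chains are low-pass).
    """

    f: np.ndarray
    h: np.ndarray
    label: str = "H"

    def __post_init__(self) -> None:
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "h", np.asarray(self.h, dtype=complex))
        if self.f.ndim != 1 or self.f.shape != self.h.shape:
            raise ValueError("f and h must be 1-D arrays of equal shape")
        if self.f.size < 2:
            raise ValueError("need at least two frequency samples")
        df = np.diff(self.f)
        if np.any(df <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.max(np.abs(df - df[0])) > 1e-6 * abs(df[0]):
            raise ValueError("frequency axis must be uniformly spaced")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("transfer function contains non-finite values")

    @property
    def delta_f(self) -> float:
        """Frequency resolution in Hz."""
        return float(self.f[1] - self.f[0])

    def sample(self, freqs: np.ndarray) -> np.ndarray:
        """Linearly interpolate H onto arbitrary frequencies, zero outside
        the tabulated band (real and imaginary parts separately)."""
        re = np.interp(freqs, self.f, self.h.real, left=0.0, right=0.0)
        im = np.interp(freqs, self.f, self.h.imag, left=0.0, right=0.0)
        return re + 1j * im


def ideal_girf(bandwidth_hz: float = 1e6, delta_f: float = 1e3,
               label: str = "Hi") -> TransferFunction:
    """Unit response over a wide band: the idealized gradient system."""
    n = int(np.ceil(bandwidth_hz / delta_f))
    f = np.arange(-n, n + 1) * delta_f
    return TransferFunction(f, np.ones_like(f, dtype=complex), label)


def synthetic_girf(cutoff_hz: float, delay_s: float = 0.0, order: int = 1,
                   delta_f: float = 76.3, bandwidth_hz: float = 50e3,
                   label: str = "Hsynth") -> TransferFunction:
    """Butterworth-magnitude low-pass with a linear phase delay.

    ``|H(f)| = (1 + (f/fc)^(2 order))^(-1/2)``, ``arg H = -2 pi f delay``.
    This emulates the low-pass character and phase delay of measured
    gradient transfer functions.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if order < 1:
        raise ValueError("order must be >= 1")
    if cutoff_hz >= bandwidth_hz:
        raise ValueError("cutoff beyond the declared bandwidth")
    n = int(np.ceil(bandwidth_hz / delta_f))
    f = np.arange(-n, n + 1) * delta_f
    mag = (1.0 + (f / cutoff_hz) ** (2 * order)) ** -0.5
    h = mag * np.exp(-2j * np.pi * f * delay_s)
    return TransferFunction(f, h, label)


def _hermitize(f: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Average H(f) with conj(H(-f)) so the impulse response is real."""
    h_rev = np.interp(-f, f, h.real, left=np.nan, right=np.nan) \
        - 1j * np.interp(-f, f, h.imag, left=np.nan, right=np.nan)
    ok = np.isfinite(h_rev.real)
    out = h.copy()
    out[ok] = 0.5 * (h[ok] + h_rev[ok])
    return out


def load_girf(source, label: str | None = None) -> TransferFunction:
    """Load a tabulated transfer function.

    Accepts a CSV path/stream with columns ``f_Hz, H_re, H_im`` (``H_im``
    optional, warned and zero-filled if missing), a ``.mat`` container, or
    a mapping with keys ``f``/``f_Hz`` and ``H`` (complex) or
    ``H_re``/``H_im``.  Hermitian symmetry of two-sided axes is enforced
    by averaging H(f) with conj(H(-f)).
    """
    if isinstance(source, dict):
        return _girf_from_mapping(source, label)
    name = getattr(source, "name", source if isinstance(source, str) else "")
    if isinstance(name, str) and name.endswith(".mat"):
        return _girf_from_mat(source, label)
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    start = 1 if lines and not _is_numeric_row(lines[0]) else 0
    data = np.genfromtxt(io.StringIO("\n".join(lines[start:])), delimiter=",")
    data = np.atleast_2d(data)
    f = data[:, 0]
    h_re = data[:, 1]
    if data.shape[1] >= 3 and np.all(np.isfinite(data[:, 2])):
        h_im = data[:, 2]
    else:
        logger.warning("GIRF file has no imaginary column; assuming real H")
        h_im = np.zeros_like(h_re)
    h = _hermitize(f, h_re + 1j * h_im)
    return TransferFunction(f, h, label or "H")


def _is_numeric_row(line: str) -> bool:
    try:
        [float(v) for v in line.split(",")]
        return True
    except ValueError:
        return False


def _girf_from_mapping(d: dict, label: str | None) -> TransferFunction:
    f = np.asarray(d.get("f_Hz", d.get("f"))).ravel().astype(float)
    if "H" in d:
        h = np.asarray(d["H"]).ravel().astype(complex)
    else:
        h = np.asarray(d["H_re"]).ravel() + 1j * np.asarray(
            d.get("H_im", np.zeros(f.size))).ravel()
    return TransferFunction(f, _hermitize(f, h), label or "H")


def _girf_from_mat(path, label: str | None) -> TransferFunction:
    """Converter for .mat containers holding the same arrays."""
    from scipy.io import loadmat
    try:
        raw = loadmat(path)
    except NotImplementedError:  # v7.3: HDF5-based container
        import h5py
        with h5py.File(path, "r") as fh:
            raw = {k: np.asarray(v) for k, v in fh.items()}
    keys = {k.lower(): k for k in raw if not k.startswith("__")}
    fkey = next(k for k in ("f_hz", "f", "freq") if k in keys)
    f = np.asarray(raw[keys[fkey]]).ravel().astype(float)
    if "h" in keys:
        h = np.asarray(raw[keys["h"]]).ravel().astype(complex)
    else:
        h = (np.asarray(raw[keys["h_re"]]).ravel()
             + 1j * np.asarray(raw[keys["h_im"]]).ravel())
    return TransferFunction(f, _hermitize(f, h), label or "H")


def save_girf(path, tf: TransferFunction) -> None:
    """Write the canonical CSV form (round-trips exactly)."""
    lines = [f"# delta_f={float(tf.delta_f)!r}", "f_Hz,H_re,H_im"]
    for fv, hv in zip(tf.f, tf.h):
        lines.append(f"{float(fv)!r},{float(hv.real)!r},{float(hv.imag)!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def average_girfs(tfs: list[TransferFunction],
                  label: str | None = None) -> TransferFunction:
    """Pointwise complex arithmetic mean of transfer functions sharing one
    frequency axis (e.g. the y/z-axis mean used when the slice orientation
    is not known in advance)."""
    if not tfs:
        raise ValueError("need at least one transfer function")
    f0 = tfs[0].f
    for tf in tfs[1:]:
        if tf.f.shape != f0.shape or np.max(np.abs(tf.f - f0)) > 1e-9:
            raise ValueError("frequency axes do not match")
    h = np.mean([tf.h for tf in tfs], axis=0)
    return TransferFunction(f0, h, label or "+".join(t.label for t in tfs))


def cutoff_frequency(tf: TransferFunction):
    """Smallest positive frequency where |H| falls to half its DC value.

    Linearly interpolated between tabulated points; returns
    :data:`NO_CUTOFF` (None) if the magnitude never reaches 1/2 inside the
    tabulated band.
    """
    mag0 = np.abs(tf.sample(np.array([0.0]))[0])
    if mag0 <= 0:
        raise ValueError("|H(0)| must be positive")
    pos = tf.f >= 0
    f = tf.f[pos]
    mag = np.abs(tf.h[pos]) / mag0
    below = np.nonzero(mag <= 0.5)[0]
    below = below[f[below] > 0]
    if below.size == 0:
        return NO_CUTOFF
    i = below[0]
    f1, f0_ = f[i], f[i - 1]
    m1, m0 = mag[i], mag[i - 1]
    if m1 == m0:
        return float(f1)
    return float(f0_ + (0.5 - m0) / (m1 - m0) * (f1 - f0_))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _padded_length(n: int) -> int:
    """Zero-pad to at least twice the signal length, next power of two, to
    suppress wrap-around of the impulse response."""
    return 1 << max(1, math.ceil(math.log2(2 * n)))


def apply_girf(grad, tf: TransferFunction, grid: TimeGrid) -> np.ndarray:
    """Realized gradient: real part of the filtered demanded gradient.

    The demanded sequence is zero-padded (gradient off before and after the
    pulse), transformed, multiplied with H interpolated onto the transform
    frequencies (zero outside its tabulated band), inverse transformed,
    and truncated back to ``Nt - 1`` real samples.
    """
    gs = grad.gs if isinstance(grad, GradientWaveform) else np.asarray(grad)
    n = grid.n_intervals
    if gs.shape != (n,):
        raise ValueError("gradient length does not match grid")
    npad = _padded_length(n)
    freqs = np.fft.fftfreq(npad, d=grid.tau)
    hs = tf.sample(freqs)
    out = ifft(fft(gs, npad) * hs)
    return np.real(out[:n])


class FilterOperator:
    """Dense linear operator of the discrete gradient filter.

    Wraps the real matrix ``Re(F^-1 diag(H) F)`` restricted to the ``Nt-1``
    pulse samples, with its transpose for adjoint computations.  Built once
    per (transfer function, grid) pair; see :func:`filter_matrix`.
    """

    def __init__(self, matrix: np.ndarray, label: str = "H"):
        self.matrix = matrix
        self.label = label

    def apply(self, gs: np.ndarray) -> np.ndarray:
        return self.matrix @ gs

    def apply_transpose(self, v: np.ndarray) -> np.ndarray:
        return self.matrix.T @ v

    __call__ = apply


_filter_cache: dict = {}


def filter_matrix(tf: TransferFunction, grid: TimeGrid,
                  cache: bool = True) -> FilterOperator:
    """Explicit dense filter operator agreeing with :func:`apply_girf`.

    The operator is Toeplitz (shift invariance of the zero-padded filter),
    so it is assembled from the response to a single unit impulse.
    """
    key = (id(tf), grid.tau, grid.nt)
    if cache and key in _filter_cache:
        cached_tf, cached_op = _filter_cache[key]
        if cached_tf is tf:  # guard against id() reuse after collection
            return cached_op
    n = grid.n_intervals
    npad = _padded_length(n)
    freqs = np.fft.fftfreq(npad, d=grid.tau)
    hs = tf.sample(freqs)
    impulse = np.zeros(npad)
    impulse[0] = 1.0
    resp = np.real(ifft(fft(impulse) * hs))
    # column j of the operator is the impulse response delayed by j samples
    # (zero-padded, so negative lags wrap to the end of resp)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % npad
    op = FilterOperator(resp[idx], tf.label)
    if cache:
        _filter_cache[key] = (tf, op)
    return op
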