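"""Flat key-value design configuration.

Keys mirror the symbols of the design specification: ``mb``, ``tbwp``,
``thk_mm``, ``fov_mm``, ``rmax_uT``, ``gmax_mT_m``, ``smax_T_m_s``,
``tau_us``, ``es``, ``ep_rad``, ``fp_hz``, ``sar_eff``, ``sar_max``,
``nz``, ``d1``, ``d2``, ``girf_file``.  Defaults are the hardware and
safety values of a 3 T whole-body system.
"""

from __future__ import annotations

from .bloch import SpatialGrid
from .girf import load_girf
from .objective import DesignProblem, ProfileBounds, SARConfig
from .pins import build_pins, build_slice_domains
from .waveforms import HardwareBounds

DEFAULTS = {
    "mb": 4,
    "tbwp": 4.0,
    "thk_mm": 2.0,
    "fov_mm": 120.0,
    "rmax_uT": 13.0,
    "gmax_mT_m": 30.0,
    "smax_T_m_s": 180.0,
    "tau_us": 6.4,
    "es": 0.02,
    "ep_rad": 0.025,
    "fp_hz": 16.67,
    "sar_eff": 0.25,
    "sar_max": 3.2,
    "nz": 1000,
    "d1": 0.01 / 4,
    "d2": 0.01 / 2,
    "girf_file": "",
}

_INT_KEYS = {"mb", "nz"}


def parse_config(path) -> dict:
    """Read a flat ``key = value`` (or ``key: value``) text file."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    params = dict(DEFAULTS)
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, val = (part.strip() for part in line.split(sep, 1))
                break
        else:
            raise ValueError(f"cannot parse config line: {line!r}")
        if key not in DEFAULTS:
            raise KeyError(f"unknown config key {key!r}")
        if key == "girf_file":
            params[key] = val
        elif key in _INT_KEYS:
            params[key] = int(val)
        else:
            params[key] = float(val)
    return params


def make_problem(params: dict):
    """Build the :class:`DesignProblem` (and hardware bounds, raster) from
    a parameter mapping with the keys above."""
    p = dict(DEFAULTS)
    p.update(params)
    hw = HardwareBounds(p["rmax_uT"] * 1e-6, p["gmax_mT_m"] * 1e-3,
                        p["smax_T_m_s"])
    tau = p["tau_us"] * 1e-6
    spec = build_slice_domains(p["mb"], p["thk_mm"] * 1e-3,
                               p["fov_mm"] * 1e-3, p["tbwp"],
                               p["d1"], p["d2"])
    space = SpatialGrid(p["fov_mm"] * 1e-3, int(p["nz"]))
    bounds = ProfileBounds.uniform(p["es"], p["ep_rad"])
    girf = load_girf(p["girf_file"]) if p.get("girf_file") else None
    sar = SARConfig(p["fp_hz"], p["sar_eff"], p["sar_max"])
    problem = DesignProblem(spec, space, hw, bounds, girf, sar)
    return problem, hw, tau


def pins_initial(params: dict, problem: DesignProblem | None = None):
    """PINS initial waveforms for a parameter mapping."""
    p = dict(DEFAULTS)
    p.update(params)
    hw = HardwareBounds(p["rmax_uT"] * 1e-6, p["gmax_mT_m"] * 1e-3,
                        p["smax_T_m_s"])
    return build_pins(p["mb"], p["thk_mm"] * 1e-3, p["fov_mm"] * 1e-3,
                      p["tbwp"], hw, p["tau_us"] * 1e-6, p["d1"], p["d2"])
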