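"""Shared fixtures: small deterministic problems and waveforms."""

import numpy as np
import pytest

from girfpulse import (ControlVector, DesignProblem, HardwareBounds,
                       ProfileBounds, SpatialGrid, TimeGrid,
                       build_slice_domains, synthetic_girf)

SCANNER_HW = HardwareBounds(rmax=13e-6, gmax=30e-3, smax=180.0)
SCANNER_TAU = 6.4e-6


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def hw():
    return SCANNER_HW


@pytest.fixture
def small_grid():
    return TimeGrid(SCANNER_TAU, 41)


@pytest.fixture
def small_space():
    return SpatialGrid(0.06, 31)


@pytest.fixture
def toy_problem(small_space, hw):
    """Two thin slices across 60 mm with explicit transition bands wide
    enough for the coarse spatial grid."""
    spec = build_slice_domains(2, 0.003, 0.06, 2, transition=0.25)
    return DesignProblem(spec, small_space, hw,
                         ProfileBounds.uniform(0.02, 0.025), girf=None)


@pytest.fixture
def lowpass_girf():
    return synthetic_girf(cutoff_hz=3750.0, delay_s=50e-6,
                          delta_f=500.0, bandwidth_hz=40e3)


@pytest.fixture
def random_controls(rng, small_grid):
    n = small_grid.n_intervals
    return ControlVector(rng.uniform(0.0, 13e-6, n),
                         rng.uniform(-np.pi, np.pi, n),
                         rng.uniform(-180.0, 180.0, n), small_grid)
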