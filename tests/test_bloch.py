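"""Spin-domain simulation against an independent rotation-matrix oracle,
closed-form hard-pulse cases, and structural properties."""

import numpy as np
import pytest

from girfpulse import (GAMMA_1H, PerturbationGrid, SpatialGrid, TimeGrid,
                       excitation_flip_angle, refocusing_profile,
                       robustness_sweep, simulate)
from girfpulse.bloch import SpinDomainProfile, compose


def bloch_rotation_oracle(b1, gs, tau, z, b1_scale=1.0, b0_offset_hz=0.0):
    """Independent reference: propagate the full 3x3 rotation matrix of
    the magnetization and map it to the crushed-SE observable.

    Each interval rotates magnetization about the effective field
    (Re B1, Im B1, z G + 2 pi df / gamma) by gamma |field| tau, built
    from Rodrigues' formula.  The crushed spin-echo refocusing efficiency
    is extracted from the transverse block of the composite rotation:
    for a rotation with Cayley-Klein pair (a, b), the matrix maps
    M+ -> a^2 M+* ... so |b^2| = |R[0,0] - R[1,1] +- ...| is recovered
    from the xy sub-block; we compare via the magnetization the pulse
    produces from M+ = 1 with perfect crushing, i.e. the b^2 pathway
    coefficient (R_xx - R_yy)/2 - i (R_xy + R_yx)/2 conjugated.
    """
    out_mag = np.empty(z.size)
    out_b2 = np.empty(z.size, dtype=complex)
    for iz, zz in enumerate(z):
        rot = np.eye(3)
        for m in range(len(b1)):
            bx = (b1[m] * b1_scale).real
            by = (b1[m] * b1_scale).imag
            bz = zz * gs[m] + 2 * np.pi * b0_offset_hz / GAMMA_1H
            field = np.array([bx, by, bz])
            norm = np.linalg.norm(field)
            angle = -GAMMA_1H * tau * norm
            if norm == 0:
                continue
            k = field / norm
            kx = np.array([[0, -k[2], k[1]],
                           [k[2], 0, -k[0]],
                           [-k[1], k[0], 0]])
            step = (np.eye(3) + np.sin(angle) * kx
                    + (1 - np.cos(angle)) * (kx @ kx))
            rot = step @ rot
        # b^2 pathway coefficient of the composite rotation acting on M+:
        # M+ -> (conj(a)^2) M+ - ... ; the coefficient multiplying conj(M+)
        # is b^2 expressed through the xy block
        b2 = ((rot[0, 0] - rot[1, 1]) / 2.0
              + 1j * (rot[0, 1] + rot[1, 0]) / 2.0)
        out_b2[iz] = b2
        out_mag[iz] = abs(b2)
    return out_mag, out_b2


class TestSimulateOracle:
    def test_matches_rotation_matrix_oracle(self, rng):
        """Spin-domain |b|^2 equals the independent 3x3 rotation
        propagation on random short waveforms to 1e-8."""
        grid = TimeGrid(6.4e-6, 31)
        space = SpatialGrid(0.04, 17)
        for _ in range(5):
            b1 = (rng.uniform(0, 13e-6, 30)
                  * np.exp(1j * rng.uniform(-np.pi, np.pi, 30)))
            gs = rng.uniform(-30e-3, 30e-3, 30)
            prof = simulate(b1, gs, grid, space)
            mag, _ = refocusing_profile(prof)
            mag_ref, _ = bloch_rotation_oracle(b1, gs, grid.tau, space.z)
            assert np.max(np.abs(mag - mag_ref)) <= 1e-8

    def test_oracle_with_perturbations(self, rng):
        grid = TimeGrid(6.4e-6, 25)
        space = SpatialGrid(0.03, 9)
        b1 = rng.uniform(0, 10e-6, 24) + 0j
        gs = rng.uniform(-20e-3, 20e-3, 24)
        prof = simulate(b1, gs, grid, space, b1_scale=0.85,
                        b0_offset_hz=120.0)
        mag, _ = refocusing_profile(prof)
        mag_ref, _ = bloch_rotation_oracle(b1, gs, grid.tau, space.z,
                                           0.85, 120.0)
        assert np.max(np.abs(mag - mag_ref)) <= 1e-8


class TestClosedForms:
    def test_no_rf_no_gradient_identity(self, small_grid, small_space):
        prof = simulate(np.zeros(small_grid.n_intervals, complex),
                        np.zeros(small_grid.n_intervals), small_grid,
                        small_space)
        np.testing.assert_allclose(prof.a, 1.0)
        np.testing.assert_allclose(prof.b, 0.0)

    def test_hard_pi_pulse_refocuses_on_resonance(self):
        """Constant real RF with gamma*r*T = pi gives |b|^2 = 1."""
        grid = TimeGrid(6.4e-6, 101)
        r = np.pi / (GAMMA_1H * grid.duration)
        space = SpatialGrid(0.01, 3)
        prof = simulate(np.full(grid.n_intervals, r, complex),
                        np.zeros(grid.n_intervals), grid, space)
        mag, _ = refocusing_profile(prof)
        np.testing.assert_allclose(mag, 1.0, atol=1e-12)

    def test_hard_pulse_scaled_down_ninefold_gives_20_degrees(self):
        """A pi pulse at 1/9 amplitude excites a 20-degree flip."""
        grid = TimeGrid(6.4e-6, 101)
        r = np.pi / (GAMMA_1H * grid.duration) / 9.0
        space = SpatialGrid(0.01, 3)
        prof = simulate(np.full(grid.n_intervals, r, complex),
                        np.zeros(grid.n_intervals), grid, space)
        flip = excitation_flip_angle(prof)
        np.testing.assert_allclose(np.degrees(flip), 20.0, rtol=1e-10)

    def test_zero_rf_no_refocusing_any_gradient(self, rng, small_grid,
                                                small_space):
        gs = rng.uniform(-30e-3, 30e-3, small_grid.n_intervals)
        prof = simulate(np.zeros(small_grid.n_intervals, complex), gs,
                        small_grid, small_space)
        assert np.all(np.abs(prof.b) == 0)


class TestProfileExtraction:
    def test_refocusing_of_pure_b_states(self):
        prof = SpinDomainProfile(np.array([1.0, 0.0, 0.0]),
                                 np.array([0.0, 1j, 1.0]))
        mag, phase = refocusing_profile(prof)
        np.testing.assert_allclose(mag, [0.0, 1.0, 1.0])
        assert phase[1] == pytest.approx(np.pi)  # arg((i)^2) = pi
        assert phase[2] == pytest.approx(0.0)

    def test_flip_angle_extremes(self):
        prof = SpinDomainProfile(np.array([1.0, 1 / np.sqrt(2)]),
                                 np.array([0.0, 1j / np.sqrt(2)]))
        flip = excitation_flip_angle(prof)
        np.testing.assert_allclose(flip, [0.0, np.pi / 2], atol=1e-12)


class TestInvariants:
    def test_unitarity_preserved_long_waveform(self, rng):
        grid = TimeGrid(6.4e-6, 10_001)
        space = SpatialGrid(0.05, 16)
        b1 = rng.uniform(0, 13e-6, grid.n_intervals) + 0j
        gs = rng.uniform(-30e-3, 30e-3, grid.n_intervals)
        prof = simulate(b1, gs, grid, space)
        assert prof.norm_error <= 1e-10

    def test_split_and_compose_equals_one_shot(self, rng):
        grid = TimeGrid(6.4e-6, 61)
        space = SpatialGrid(0.04, 21)
        b1 = (rng.uniform(0, 13e-6, 60)
              * np.exp(1j * rng.uniform(-np.pi, np.pi, 60)))
        gs = rng.uniform(-30e-3, 30e-3, 60)
        half = TimeGrid(6.4e-6, 31)
        p1 = simulate(b1[:30], gs[:30], half, space)
        p2 = simulate(b1[30:], gs[30:], half, space)
        whole = simulate(b1, gs, grid, space)
        combined = compose(p1, p2)
        np.testing.assert_allclose(combined.a, whole.a, atol=1e-10)
        np.testing.assert_allclose(combined.b, whole.b, atol=1e-10)


class TestRobustnessSweep:
    def test_nominal_point_matches_plain_simulate(self, rng):
        grid = TimeGrid(6.4e-6, 41)
        space = SpatialGrid(0.04, 15)
        b1 = rng.uniform(0, 10e-6, 40) + 0j
        gs = rng.uniform(-20e-3, 20e-3, 40)
        mag, phase = robustness_sweep(b1, gs, grid, space,
                                      PerturbationGrid((1.0,), (0.0,)))
        ref_mag, ref_phase = refocusing_profile(
            simulate(b1, gs, grid, space))
        np.testing.assert_array_equal(mag[0, 0], ref_mag)
        np.testing.assert_array_equal(phase[0, 0], ref_phase)

    def test_entries_match_per_point_calls(self, rng):
        grid = TimeGrid(6.4e-6, 21)
        space = SpatialGrid(0.04, 9)
        b1 = rng.uniform(0, 10e-6, 20) + 0j
        gs = rng.uniform(-20e-3, 20e-3, 20)
        perturb = PerturbationGrid((0.8, 1.1), (-150.0, 0.0, 75.0))
        mag, phase = robustness_sweep(b1, gs, grid, space, perturb)
        for i, s in enumerate(perturb.b1_scales):
            for j, df in enumerate(perturb.b0_offsets_hz):
                m, p = refocusing_profile(
                    simulate(b1, gs, grid, space, s, df))
                np.testing.assert_array_equal(mag[i, j], m)
                np.testing.assert_array_equal(phase[i, j], p)

    def test_symmetric_pulse_even_magnitude(self):
        """A symmetric real pulse under a symmetric gradient produces a
        magnitude profile even in z at zero offset."""
        grid = TimeGrid(6.4e-6, 33)
        space = SpatialGrid(0.04, 32)
        t = np.arange(32)
        b1 = (6e-6 * np.exp(-((t - 15.5) / 6.0) ** 2)).astype(complex)
        gs = np.full(32, 10e-3)
        mag, _ = robustness_sweep(b1, gs, grid, space,
                                  PerturbationGrid((1.0,), (0.0,)))
        np.testing.assert_allclose(mag[0, 0], mag[0, 0][::-1], atol=1e-10)
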