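"""Correlation engine, HB kinetics, dipole reorientation, and VDOS."""

import numpy as np
import pytest

from aquadyn.dynamics import (
    CorrelationFunction,
    correlate,
    continuous_hb_tcf,
    dipole_tcf,
    dipole_vectors,
    fit_biexponential,
    hb_lifetime,
    vacf_spectrum,
    vdos,
)
from aquadyn.structure import HBCriteria
from aquadyn.synthetic import gen_dipole_series, gen_hb_event_series
from aquadyn.traj_io import Trajectory, build_water_topology

from conftest import make_single_frame


def naive_correlate(series, dt, window, origin_stride=1, kernel="dot"):
    """Independent double-loop oracle mirroring the engine's reduction
    order (per-origin contribution rows summed at the end)."""
    series = np.asarray(series)
    n_frames = series.shape[0]
    n_lags = int(round(window / dt)) + 1
    origins = list(range(0, n_frames - n_lags + 1, origin_stride))
    num = np.zeros((len(origins), n_lags))
    weights = np.zeros(len(origins))
    for oi, t0 in enumerate(origins):
        if kernel == "dot":
            n_e = series.shape[1]
            contrib = np.empty((n_lags, n_e))
            for lag in range(n_lags):
                for e in range(n_e):
                    u, v = series[t0, e], series[t0 + lag, e]
                    contrib[lag, e] = v[0] * u[0] + v[1] * u[1] + v[2] * u[2]
            num[oi] = np.sum(contrib, axis=1)
            weights[oi] = n_e
        else:
            n_e = series.shape[1]
            contrib = np.empty((n_lags, n_e))
            for e in range(n_e):
                alive = 1.0
                for lag in range(n_lags):
                    alive *= series[t0 + lag, e]
                    contrib[lag, e] = alive * series[t0, e]
            num[oi] = np.sum(contrib, axis=1)
            weights[oi] = float(np.sum(series[t0]))
    values = np.sum(num, axis=0) / np.sum(weights)
    return values


class TestCorrelate:
    def test_constant_vectors_give_unity(self):
        u = np.tile(np.array([0.0, 0, 1.0]), (20, 7, 1))
        c = correlate(u, dt=1.0, window=10.0)
        np.testing.assert_allclose(c.values, 1.0)

    def test_alternating_vectors(self):
        u = np.zeros((10, 3, 3))
        u[:, :, 0] = (-1.0) ** np.arange(10)[:, None]
        c = correlate(u, dt=1.0, window=5.0)
        np.testing.assert_allclose(c.values, (-1.0) ** np.arange(6))

    @pytest.mark.parametrize("kernel", ["dot", "survival"])
    def test_matches_naive_double_loop_bitwise(self, kernel):
        rng = np.random.default_rng(1)
        if kernel == "dot":
            series = rng.normal(size=(50, 10, 3))
            series /= np.linalg.norm(series, axis=2, keepdims=True)
        else:
            series = (rng.random((50, 10)) < 0.8).astype(np.int8)
            series[0] = 1
        c = correlate(series, dt=0.1, window=2.0, origin_stride=3, kernel=kernel)
        oracle = naive_correlate(series, 0.1, 2.0, origin_stride=3, kernel=kernel)
        np.testing.assert_array_equal(c.values, oracle)

    def test_window_longer_than_series_errors(self):
        u = np.zeros((5, 2, 3))
        u[:, :, 2] = 1.0
        with pytest.raises(ValueError, match="window"):
            correlate(u, dt=1.0, window=10.0)

    def test_normalized_tcf_starts_at_one(self):
        u = gen_dipole_series(50, 0.05, 0.01, 100, seed=0)
        c = correlate(u, 0.01, window=0.5)
        assert c.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(c.values) <= 1.0 + 1e-12)


class TestContinuousHB:
    def _bonded_dimer_traj(self, n_frames=30, break_at=None):
        frames = []
        for f in range(n_frames):
            sep = 2.8 if break_at is None or f < break_at else 4.5
            o1 = [10.0, 10, 10]
            frames.append(
                [
                    o1, [10.957, 10, 10], [9.76, 10.59, 10],
                    [10 + sep, 10, 10], [10 + sep + 0.957, 10, 10],
                    [10 + sep - 0.24, 10.59, 10],
                ]
            )
        return Trajectory(
            dt=0.1, cell=np.full((n_frames, 3), 30.0),
            elements=np.array(["O", "H", "H", "O", "H", "H"]),
            positions=np.array(frames),
        )

    def test_permanent_bond_survives(self):
        traj = self._bonded_dimer_traj()
        topo = build_water_topology(traj)
        S = continuous_hb_tcf(traj, topo, HBCriteria(), window=2.0)
        np.testing.assert_allclose(S.values, 1.0)

    def test_broken_bond_steps_to_zero(self):
        traj = self._bonded_dimer_traj(break_at=10)
        topo = build_water_topology(traj)
        S = continuous_hb_tcf(traj, topo, HBCriteria(), window=1.5)
        # bond alive for 10 frames: survival is positive for shorter lags and
        # exactly zero from the 10-frame lag on (never reformed)
        assert np.all(S.values[S.lags < 1.0 - 1e-9] > 0)
        np.testing.assert_allclose(S.values[S.lags >= 1.0 - 1e-9], 0.0)

    def test_no_bonds_is_an_error(self):
        traj = self._bonded_dimer_traj()
        traj.positions[:, 3:, 0] += 10.0  # move the partner out of range
        topo = build_water_topology(traj)
        with pytest.raises(ValueError, match="no hydrogen bonds"):
            continuous_hb_tcf(traj, topo, HBCriteria(), window=1.0)

    def test_poisson_breaking_recovers_rate(self):
        k, dt = 0.5, 0.05
        h = gen_hb_event_series(2000, k, dt, 300, seed=2)
        S = correlate(h, dt, window=11.0, kernel="survival")
        ref = np.exp(-k * S.lags)
        assert np.max(np.abs(S.values - ref)) < 0.05
        tau = hb_lifetime(S)
        assert tau == pytest.approx(1.0 / k, rel=0.05)


class TestHBLifetime:
    def test_exponential_closed_form_with_tail(self):
        t = np.arange(0, 11.0001, 0.01)
        S = CorrelationFunction(t, np.exp(-t / 1.5), np.ones_like(t), 11.0)
        assert hb_lifetime(S) == pytest.approx(1.5, abs=0.01)

    def test_constant_survival_without_tail(self):
        t = np.arange(0, 11.0001, 0.01)
        S = CorrelationFunction(t, np.ones_like(t), np.ones_like(t), 11.0)
        assert hb_lifetime(S, tail="none") == pytest.approx(11.0)

    def test_two_rate_mixture_matches_quadrature(self):
        t = np.arange(0, 11.0001, 0.005)
        y = 0.6 * np.exp(-t / 0.8) + 0.4 * np.exp(-t / 3.0)
        S = CorrelationFunction(t, y, np.ones_like(t), 11.0)
        got = hb_lifetime(S, tail="none")
        expected = np.trapezoid(y, t)
        assert got == pytest.approx(expected, rel=1e-10)
        # with the tail correction, approach the infinite-time integral
        assert hb_lifetime(S) == pytest.approx(0.6 * 0.8 + 0.4 * 3.0, rel=0.01)


class TestDipoles:
    def test_symmetric_water_points_along_z(self):
        pos = np.array([[5.0, 5, 5], [5.76, 5, 5.59], [4.24, 5, 5.59]])
        traj = make_single_frame(["O", "H", "H"], pos)
        topo = build_water_topology(traj)
        mu = dipole_vectors(traj.positions[0], topo, traj.cell[0])
        np.testing.assert_allclose(mu[0], [0, 0, 1], atol=1e-12)

    def test_rotation_equivariance_and_unit_norm(self):
        rng = np.random.default_rng(4)
        pos = np.array([[5.0, 5, 5], [5.76, 5, 5.59], [4.24, 5, 5.59]])
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=7).as_matrix()
        center = pos[0]
        pos_rot = (pos - center) @ R.T + center
        traj1 = make_single_frame(["O", "H", "H"], pos)
        traj2 = make_single_frame(["O", "H", "H"], pos_rot)
        topo = build_water_topology(traj1)
        mu1 = dipole_vectors(traj1.positions[0], topo, traj1.cell[0])
        mu2 = dipole_vectors(traj2.positions[0], topo, traj2.cell[0])
        np.testing.assert_allclose(mu2[0], R @ mu1[0], atol=1e-10)
        assert np.linalg.norm(mu1[0]) == pytest.approx(1.0)

    def test_degenerate_geometry_errors(self):
        pos = np.array([[5.0, 5, 5], [5.0, 5, 4.2], [5.0, 5, 5.8]])
        traj = make_single_frame(["O", "H", "H"], pos)
        topo = build_water_topology(traj)
        with pytest.raises(ValueError, match="degenerate"):
            dipole_vectors(traj.positions[0], topo, traj.cell[0])

    def test_frozen_waters_keep_full_correlation(self):
        pos = np.array([[5.0, 5, 5], [5.76, 5, 5.59], [4.24, 5, 5.59]])
        traj = Trajectory(
            dt=0.1, cell=np.full((20, 3), 20.0),
            elements=np.array(["O", "H", "H"]),
            positions=np.tile(pos, (20, 1, 1)),
        )
        topo = build_water_topology(traj)
        c = dipole_tcf(traj, topo, window=1.0)
        np.testing.assert_allclose(c.values, 1.0)

    def test_rotational_diffusion_closed_form(self):
        D, dt, n = 0.05, 0.01, 500
        u = gen_dipole_series(n, D, dt, 2001, seed=6)  # 20 ps span
        c = correlate(u, dt, window=10.0, origin_stride=10)
        ref = np.exp(-2 * D * c.lags)
        # pointwise sampling envelope: each dipole contributes roughly
        # (1 + 2 D span) independent samples over the trajectory
        n_eff = n * (1 + 2 * D * 20.0)
        envelope = 3 * np.sqrt(np.clip(1 - ref**2, 1e-12, None) / n_eff)
        assert np.all(np.abs(c.values - ref) <= envelope + 5e-3)
        # and the fitted reorientation time recovers 1/(2D) within 5%
        from aquadyn.dynamics import fit_biexponential

        fit = fit_biexponential(c, fit_start=0.0)
        assert fit.tau_reor == pytest.approx(1 / (2 * D), rel=0.05)


class TestBiExpFit:
    def test_exact_curve_recovers_tau_reor(self):
        t = np.arange(0, 16, 0.02)
        y = 0.7 * np.exp(-t / 2) + 0.3 * np.exp(-t / 8)
        fit = fit_biexponential(
            CorrelationFunction(t, y, np.ones_like(t), 16.0), fit_start=0.0
        )
        assert fit.tau_reor == pytest.approx(3.8, rel=1e-4)
        assert (fit.a, fit.b) == pytest.approx((0.7, 0.3), rel=1e-3)

    def test_single_exponential_fallback(self):
        t = np.arange(0, 16, 0.02)
        fit = fit_biexponential(
            CorrelationFunction(t, np.exp(-t / 3), np.ones_like(t), 16.0),
            fit_start=0.0,
        )
        assert fit.tau_reor == pytest.approx(3.0, rel=0.01)
        assert fit.b == 0.0

    def test_noisy_biexponential_within_ten_percent(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 16, 0.02)
        y = 0.7 * np.exp(-t / 2) + 0.3 * np.exp(-t / 8)
        yn = y + 0.005 * rng.normal(size=t.size)
        fit = fit_biexponential(
            CorrelationFunction(t, yn, np.ones_like(t), 16.0), fit_start=0.0
        )
        assert fit.a == pytest.approx(0.7, rel=0.1)
        assert fit.b == pytest.approx(0.3, rel=0.1)
        assert fit.tau1 == pytest.approx(2.0, rel=0.1)
        assert fit.tau2 == pytest.approx(8.0, rel=0.1)

    def test_tau_reor_is_amplitude_weighted_mean(self):
        t = np.arange(0, 16, 0.02)
        y = 0.5 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 5.0)
        fit = fit_biexponential(
            CorrelationFunction(t, y, np.ones_like(t), 16.0), fit_start=0.0
        )
        assert fit.tau_reor == pytest.approx(
            (fit.a * fit.tau1 + fit.b * fit.tau2) / (fit.a + fit.b)
        )


class TestVDOS:
    def _tone_velocities(self, wavenumbers_cm1, n_frames=2000, dt=0.002, n_atoms=4):
        c = 0.0299792458  # cm/ps
        t = np.arange(n_frames) * dt
        v = np.zeros((n_frames, n_atoms, 3))
        for k, wn in enumerate(np.atleast_1d(wavenumbers_cm1)):
            f = wn * c  # cycles/ps
            v[:, :, k % 3] += np.cos(2 * np.pi * f * t)[:, None]
        return v

    def test_pure_tone_peak_within_one_bin(self):
        v = self._tone_velocities(250.0)
        wn, spec = vacf_spectrum(v, dt=0.002, window=2.0)
        bin_width = wn[1] - wn[0]
        assert abs(wn[np.argmax(spec)] - 250.0) <= bin_width

    def test_two_tones_two_peaks(self):
        v = self._tone_velocities([150.0, 600.0])
        wn, spec = vacf_spectrum(v, dt=0.002, window=2.0)
        bin_width = wn[1] - wn[0]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(spec, height=0.3 * spec.max())
        found = sorted(wn[p] for p in peaks)
        assert len(found) == 2
        assert abs(found[0] - 150.0) <= bin_width
        assert abs(found[1] - 600.0) <= bin_width

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=(3000, 30, 3))
        wn, spec = vacf_spectrum(v, dt=0.002, window=1.0)
        body = spec[1:-1]
        assert body.std() / body.mean() < 0.2

    def test_missing_velocities_errors(self, toy_configs):
        traj = toy_configs["monomer"].trajectory
        with pytest.raises(ValueError, match="velocities"):
            vdos(traj, window=0.5)

    def test_species_resolved_on_trajectory(self):
        rng = np.random.default_rng(8)
        pos = np.array([[5.0, 5, 5], [5.76, 5, 5.59], [4.24, 5, 5.59]])
        n_frames = 1000
        traj = Trajectory(
            dt=0.002, cell=np.full((n_frames, 3), 20.0),
            elements=np.array(["O", "H", "H"]),
            positions=np.tile(pos, (n_frames, 1, 1)),
            velocities=rng.normal(size=(n_frames, 3, 3)),
        )
        spec = vdos(traj, window=0.5)
        assert set(spec.intensity) == {"O", "H", "total"}
        np.testing.assert_allclose(
            spec.total, spec.intensity["O"] + spec.intensity["H"]
        )
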