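"""Confined Brownian/fBm dynamics and the synthetic intensity traces."""

import numpy as np
import pytest

from confcs.geometry import CellGeometry, ConfocalVolume, psf_intensity
from confcs.simulate import (
    MotionModel,
    SimulationConfig,
    evolve_positions,
    gamma_from_diffusion,
    generate_fgn,
    sample_uniform_positions,
    simulate_trace,
    step_brownian,
)


class TestStepBrownian:
    def test_zero_diffusion_leaves_positions(self, rng):
        geom = CellGeometry(5.0, 0.8)
        pos = sample_uniform_positions(20, geom, rng)
        out = step_brownian(pos, MotionModel.brownian(0.0), 1e-6, geom, rng)
        assert np.array_equal(out, pos)

    def test_free_space_msd_slope(self, rng):
        # effectively unconfined: cell much larger than the walk extent
        geom = CellGeometry(L=2e6, d=1e6)
        D, dt = 10.0, 1e-3
        n_particles, n_steps = 1000, 100
        pos = np.zeros((n_particles, 3))
        msd = np.empty(n_steps)
        cur = pos.copy()
        for t in range(n_steps):
            cur = step_brownian(cur, MotionModel.brownian(D), dt, geom, rng)
            msd[t] = np.mean(np.sum(cur**2, axis=1))
        times = dt * np.arange(1, n_steps + 1)
        slope = float(np.sum(times * msd) / np.sum(times**2))
        assert slope == pytest.approx(6.0 * D, rel=0.02)

    def test_outputs_stay_inside(self, rng):
        geom = CellGeometry(5.0, 0.7)
        pos = sample_uniform_positions(200, geom, rng)
        for _ in range(50):
            pos = step_brownian(pos, MotionModel.brownian(30.0), 1e-4, geom, rng)
            assert np.all(geom.contains(pos))


class TestOccupancy:
    def test_uniform_over_spherocylinder(self, rng):
        # stationary law: the fraction of particles in the cylindrical part
        # equals the cylinder volume fraction
        geom = CellGeometry(5.0, 0.85)
        n = 6000
        pos = sample_uniform_positions(n, geom, rng)
        pos = evolve_positions(pos, D=20.0, dt=1e-5, n_steps=2000, geom=geom, seed=7)
        frac_cyl = (geom.L - geom.d) * np.pi * geom.radius**2 / geom.volume
        observed = np.mean(np.abs(pos[:, 0]) <= geom.half_cylinder_length)
        se = np.sqrt(frac_cyl * (1 - frac_cyl) / n)
        assert abs(observed - frac_cyl) < 3 * se

    def test_redraw_and_reflect_agree(self, rng):
        # the two boundary rules preserve the same stationary occupancy
        from scipy.stats import ks_2samp

        geom = CellGeometry(5.0, 0.8)
        n = 4000
        start = sample_uniform_positions(n, geom, rng)
        a = evolve_positions(start, 20.0, 1e-5, 1500, geom, boundary="redraw", seed=11)
        b = evolve_positions(start, 20.0, 1e-5, 1500, geom, boundary="reflect", seed=12)
        r_a = np.hypot(a[:, 1], a[:, 2])
        r_b = np.hypot(b[:, 1], b[:, 2])
        assert ks_2samp(r_a, r_b).pvalue > 0.01
        assert ks_2samp(a[:, 0], b[:, 0]).pvalue > 0.01


class TestFractionalGaussianNoise:
    def test_alpha_one_is_white_noise(self, rng):
        gamma, dt = 2.0, 1e-3
        x = generate_fgn(1 << 14, 1.0, gamma, dt, rng, n_series=4)
        var = x.var(axis=1).mean()
        assert var == pytest.approx(gamma * dt, rel=0.05)
        lag1 = np.mean([np.mean(s[1:] * s[:-1]) for s in x])
        assert abs(lag1) < 3 * gamma * dt / np.sqrt(x.shape[1])

    def test_autocovariance_matches_formula(self, rng):
        alpha, gamma, dt = 0.8, 2.0, 1e-3
        n, reps = 1 << 13, 64
        x = generate_fgn(n, alpha, gamma, dt, rng, n_series=reps)
        scale = gamma * dt**alpha
        for lag in range(1, 6):
            per_series = np.mean(x[:, lag:] * x[:, :-lag], axis=1)
            mean = per_series.mean()
            se = per_series.std(ddof=1) / np.sqrt(reps)
            expected = scale * 0.5 * (
                (lag + 1) ** alpha + (lag - 1) ** alpha - 2.0 * lag**alpha
            )
            assert abs(mean - expected) < 3 * se + 1e-12

    def test_cumsum_msd_exponent(self, rng):
        alpha, gamma, dt = 0.8, 1.0, 1e-3
        n, reps = 1 << 14, 200
        x = generate_fgn(n, alpha, gamma, dt, rng, n_series=reps)
        paths = np.cumsum(x, axis=1)
        idx = np.unique(np.geomspace(1, n - 1, 24).astype(int))
        msd = np.array([np.mean(paths[:, i] ** 2) for i in idx])
        fit = np.polyfit(np.log(idx * dt), np.log(msd), 1)
        assert fit[0] == pytest.approx(alpha, abs=0.03)

    def test_alpha_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            generate_fgn(100, 1.2, 1.0, 1e-3, rng)
        with pytest.raises(ValueError):
            generate_fgn(100, 0.0, 1.0, 1e-3, rng)

    def test_gamma_matches_brownian_at_alpha_one(self, rng):
        # Γ = 2D makes the α=1 fGn step variance equal the Brownian one
        D, dt = 5.0, 1e-4
        x = generate_fgn(1 << 14, 1.0, 2.0 * D, dt, rng, n_series=2)
        assert x.var() == pytest.approx(2.0 * D * dt, rel=0.05)

    def test_gamma_from_diffusion_matching(self):
        g = gamma_from_diffusion(10.0, 0.95, t_match=1e-3)
        # 3 Γ t^α = 6 D t at the matching time
        assert 3 * g * 1e-3**0.95 == pytest.approx(6 * 10.0 * 1e-3, rel=1e-12)


class TestSimulateTrace:
    def test_immobile_particle_at_focus_gives_unit_trace(self):
        geom = CellGeometry(5.0, 0.85)
        center = (-1.5, 0.0, 0.0)
        config = SimulationConfig(
            n_particles=1, dt=1e-4, duration=0.01, geometry=geom,
            confocal=ConfocalVolume(center=center),
            motion=MotionModel.brownian(0.0), seed=0,
        )
        trace = simulate_trace(config, initial_positions=np.array([center]))
        assert np.allclose(trace.values, 1.0)

    def test_default_confocal_center_one_micron_from_edge(self):
        config = SimulationConfig(duration=1e-4, dt=1e-6)
        assert config.confocal.center[0] == pytest.approx(-config.geometry.L / 2 + 1.0)

    def test_trace_shape_and_bounds(self):
        config = SimulationConfig(
            n_particles=50, dt=1e-5, duration=0.05,
            geometry=CellGeometry(5.0, 0.85),
            motion=MotionModel.brownian(10.0), seed=3,
        )
        trace = simulate_trace(config)
        assert trace.values.size == 5000
        assert np.all(trace.values >= 0.0)
        assert np.all(trace.values <= 50.0)

    def test_deterministic_given_seed(self):
        config = SimulationConfig(
            n_particles=10, dt=1e-5, duration=0.02,
            motion=MotionModel.brownian(10.0), seed=42,
        )
        a = simulate_trace(config)
        b = simulate_trace(config)
        assert np.array_equal(a.values, b.values)

    def test_fbm_deterministic_given_seed(self):
        config = SimulationConfig(
            n_particles=4, dt=1e-5, duration=0.02,
            motion=MotionModel.fbm(0.9, 5.0), seed=42, boundary="reflect",
        )
        a = simulate_trace(config)
        b = simulate_trace(config)
        assert np.array_equal(a.values, b.values)

    def test_mean_intensity_matches_volume_integral(self, rng):
        # time average ~ N * <I_G>_cell, with the PSF integral evaluated by
        # Monte-Carlo quadrature over the cell volume
        geom = CellGeometry(5.0, 0.85)
        conf = ConfocalVolume(center=(-1.5, 0.0, 0.0))
        config = SimulationConfig(
            n_particles=50, dt=1e-4, duration=3.0, geometry=geom,
            confocal=conf, motion=MotionModel.brownian(10.0), seed=5,
        )
        trace = simulate_trace(config)
        pts = sample_uniform_positions(400_000, geom, rng)
        expected = 50.0 * psf_intensity(pts, conf).mean()
        assert trace.values.mean() == pytest.approx(expected, rel=0.05)

    def test_stationarity_of_bleach_free_trace(self):
        config = SimulationConfig(
            n_particles=50, dt=1e-4, duration=4.0,
            geometry=CellGeometry(5.0, 0.85),
            motion=MotionModel.brownian(10.0), seed=8,
        )
        v = simulate_trace(config).values
        half = v.size // 2
        a, b = v[:half], v[half:]
        # SE of the halves' difference, de-correlated via block means
        blocks_a = a.reshape(40, -1).mean(axis=1)
        blocks_b = b.reshape(40, -1).mean(axis=1)
        se = np.sqrt(blocks_a.var(ddof=1) / 40 + blocks_b.var(ddof=1) / 40)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_bleaching_darkens_trace(self):
        base = dict(
            n_particles=50, dt=1e-4, duration=4.0,
            geometry=CellGeometry(5.0, 0.85),
            motion=MotionModel.brownian(10.0), seed=13,
        )
        free = simulate_trace(SimulationConfig(**base))
        bleached = simulate_trace(SimulationConfig(**base, bleach_rate=3.0))
        assert bleached.meta["n_bleached"] > 0
        n = free.values.size
        ratio_late = bleached.values[-n // 4 :].mean() / free.values[-n // 4 :].mean()
        ratio_early = bleached.values[: n // 4].mean() / free.values[: n // 4].mean()
        assert ratio_late < ratio_early < 1.01

    def test_confocal_center_outside_cell_rejected(self):
        config = SimulationConfig(
            duration=1e-4, dt=1e-6,
            confocal=ConfocalVolume(center=(10.0, 0.0, 0.0)),
        )
        with pytest.raises(ValueError):
            simulate_trace(config)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=1.5e-6, dt=1e-6)  # non-integer steps
        with pytest.raises(ValueError):
            SimulationConfig(n_particles=0, duration=1e-5, dt=1e-6)
        with pytest.raises(ValueError):
            SimulationConfig(
                duration=1e-5, dt=1e-6,
                motion=MotionModel.fbm(0.9, 1.0), boundary="redraw",
            )
        with pytest.raises(ValueError):
            MotionModel(kind="fbm", D=1.0)
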