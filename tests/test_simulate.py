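"""Euler--Maruyama schemes: single steps, ensembles, pairing, determinism."""

import numpy as np
import pytest

import divdrift as dd


class TestSingleSteps:
    def test_naive_drift_only_when_noise_vanishes(self, power_field):
        x = np.array([1.0, 1.0])
        out = dd.em_step_naive(x, power_field, dt=1e-3, xi=np.zeros(2))
        assert np.allclose(out, [1.00001, 1.00001])

    def test_corrected_adds_divergence_to_drift(self, power_field):
        x = np.array([1.0, 1.0])
        out = dd.em_step_corrected(x, power_field, dt=1e-3, xi=np.zeros(2))
        # drift (a + 7b) x^7|x=1 = 0.017 per component
        assert np.allclose(out, [1.000017, 1.000017])

    def test_corrected_environment_step_is_driftless(self, env_field):
        x = np.array([0.37, -1.2])
        out = dd.em_step_corrected(x, env_field, dt=0.05, xi=np.zeros(2))
        assert np.array_equal(out, x)

    def test_pure_advection_step(self):
        f = dd.constant_field((1.0, 0.0), np.zeros((2, 2)))
        x = np.array([2.0, -1.0])
        out = dd.em_step_naive(x, f, dt=0.5, xi=np.array([3.0, -4.0]))
        assert np.allclose(out, [2.5, -1.0])

    def test_constant_diffusion_makes_schemes_agree_pointwise(self):
        f = dd.constant_field((0.1, -0.2), np.diag([0.3, 0.4]))
        x = np.array([0.5, 0.5])
        xi = np.array([1.3, -0.7])
        a = dd.em_step_naive(x, f, 0.01, xi)
        b = dd.em_step_corrected(x, f, 0.01, xi)
        assert np.array_equal(a, b)

    def test_nonpositive_dt_rejected(self, power_field):
        with pytest.raises(ValueError):
            dd.em_step_naive(np.ones(2), power_field, 0.0, np.zeros(2))


class TestEnsembles:
    def test_trivial_field_keeps_start_position(self):
        f = dd.constant_field((0.0, 0.0), np.zeros((2, 2)))
        cfg = dd.SimulationConfig(x0=(0.3, 0.4), n_steps=1, n_realisations=1)
        ens = dd.simulate_ensemble(cfg, f)
        assert np.allclose(ens.finals, [[0.3, 0.4]])

    def test_same_seed_is_bitwise_reproducible(self, power_field):
        cfg = dd.SimulationConfig(n_realisations=500, n_steps=50, seed=9)
        a = dd.simulate_ensemble(cfg, power_field)
        b = dd.simulate_ensemble(cfg, power_field)
        assert np.array_equal(a.positions, b.positions)

    def test_final_only_record_matches_full_record(self, power_field):
        full = dd.SimulationConfig(n_realisations=200, n_steps=40, seed=5)
        fin = dd.SimulationConfig(n_realisations=200, n_steps=40, seed=5,
                                  record="final")
        a = dd.simulate_ensemble(full, power_field)
        b = dd.simulate_ensemble(fin, power_field)
        assert np.array_equal(a.finals, b.finals)
        assert b.positions.shape[1] == 2

    def test_brownian_limit_moments(self):
        # A = 0, D = sigma^2 I: exact scheme law is Gaussian with
        # mean x0 and covariance 2 sigma^2 T per axis
        sigma2, T, K = 0.05, 1.0, 10_000
        f = dd.constant_field((0.0, 0.0), sigma2 * np.eye(2))
        cfg = dd.SimulationConfig(x0=(0.0, 0.0), T=T, n_steps=100,
                                  n_realisations=K, seed=11, record="final")
        ens = dd.simulate_ensemble(cfg, f)
        cov = np.cov(ens.finals.T)
        assert np.allclose(np.diag(cov), 2 * sigma2 * T, rtol=0.05)
        se = np.sqrt(2 * sigma2 * T / K)
        assert np.all(np.abs(ens.finals.mean(axis=0)) < 3 * se)

    def test_constant_drift_recovers_mean_displacement(self):
        A = np.array([0.4, -0.1])
        f = dd.constant_field(A, 0.01 * np.eye(2))
        K = 10_000
        cfg = dd.SimulationConfig(x0=(0.0, 0.0), T=1.0, n_steps=50,
                                  n_realisations=K, seed=12, record="final")
        ens = dd.simulate_ensemble(cfg, f)
        se = np.sqrt(2 * 0.01 / K)
        assert np.all(np.abs(ens.finals.mean(axis=0) - A) < 3 * se)

    def test_guard_counts_negative_diffusion_clamps(self, power_field):
        cfg = dd.SimulationConfig(x0=(-1.0, -1.0), n_steps=5, n_realisations=10,
                                  seed=1)
        ens = dd.simulate_ensemble(cfg, power_field)
        assert ens.guard.clamped > 0
        assert np.all(np.isfinite(ens.positions))

    def test_reflecting_box_confines_paths(self):
        f = dd.constant_field((0.0, 0.0), np.eye(2))
        cfg = dd.SimulationConfig(x0=(0.0, 0.0), T=1.0, n_steps=200,
                                  n_realisations=300, seed=2,
                                  domain_box=(-0.5, 0.5))
        ens = dd.simulate_ensemble(cfg, f)
        assert ens.positions.min() >= -0.5
        assert ens.positions.max() <= 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_realisations": 0},
            {"n_steps": 0},
            {"T": 0.0},
            {"scheme": "milstein"},
            {"noise_mode": "antithetic"},
            {"record": "sparse"},
            {"domain_box": (1.0, -1.0)},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            dd.SimulationConfig(**kwargs)


class TestPairing:
    def test_requires_shared_noise_mode(self, power_field):
        cfg = dd.SimulationConfig(n_realisations=2)
        with pytest.raises(ValueError, match="shared"):
            dd.simulate_paired(cfg, power_field)

    def test_one_step_difference_is_divergence_times_dt(self, power_field):
        cfg = dd.SimulationConfig(n_realisations=100, noise_mode="shared", seed=3)
        naive, corrected = dd.simulate_paired(cfg, power_field)
        diff = corrected.positions[:, 1, :] - naive.positions[:, 1, :]
        expected = power_field.div_diffusion_at(np.array([1.0, 1.0])) * cfg.dt
        assert np.allclose(diff, expected, rtol=0, atol=1e-15)

    def test_constant_diffusion_paths_bitwise_identical(self):
        f = dd.constant_field((0.2, 0.1), np.diag([0.3, 0.3]))
        cfg = dd.SimulationConfig(n_realisations=200, n_steps=100,
                                  noise_mode="shared", seed=4)
        naive, corrected = dd.simulate_paired(cfg, f)
        assert np.array_equal(naive.positions, corrected.positions)

    def test_parallel_shift_structure_in_positive_quadrant(self, power_field):
        # div D > 0 componentwise for x > 0, so the corrected path stays
        # ahead of its shared-noise naive partner at every recorded time
        cfg = dd.SimulationConfig(n_realisations=100, noise_mode="shared", seed=6)
        naive, corrected = dd.simulate_paired(cfg, power_field)
        diff = corrected.positions[:, 1:, :] - naive.positions[:, 1:, :]
        assert np.all(diff > 0)


class TestTextExport:
    def test_track_and_final_round_trip(self, tmp_path, power_field):
        cfg = dd.SimulationConfig(n_realisations=3, n_steps=4, seed=8)
        ens = dd.simulate_ensemble(cfg, power_field)
        p = tmp_path / "tracks.tsv"
        ens.write_tracks(p)
        rows = np.loadtxt(p, skiprows=1)
        assert rows.shape == (3 * 5, 4)
        q = tmp_path / "finals.tsv"
        ens.write_finals(q)
        assert np.allclose(np.loadtxt(q, skiprows=1), ens.finals)
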