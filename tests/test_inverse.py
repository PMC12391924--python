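"""Classical inverse solvers against independent optimization oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from meginverse import (
    SensorRecording,
    SourceActivity,
    estimate_covariance,
    make_scenario,
    render_source_activity,
    simulate_recording,
    solve_eloreta,
    solve_lcmv,
    solve_mne,
    solve_rv_scan,
)
from meginverse.errors import (
    InsufficientDataError,
    NumericalConditioningError,
)
from meginverse.forward import Leadfield
from meginverse.geometry import SensorArray, SourceSpace


def _toy_leadfield(s, d, rng, scale=1.0):
    """Random dense leadfield with physically plausible geometry attached."""
    from meginverse import build_sensor_helmet, build_source_grid

    sensors = build_sensor_helmet(s, radius=0.12)
    # geometry is a carrier; the gain matrix is what the solvers consume
    spacing = 0.03
    grid = build_source_grid(radius=0.07, spacing=spacing, orientation_seed=0)
    positions = grid.positions[1 : d + 1]
    orientations = grid.orientations[1 : d + 1]
    space = SourceSpace(positions=positions, orientations=orientations, spacing=spacing)
    gain = rng.normal(size=(s, d)) * scale
    return Leadfield(gain=gain, sensors=sensors, sources=space)


class TestEstimateCovariance:
    def test_constant_recording_gives_zero_covariance(self):
        rec = SensorRecording(samples=np.ones((4, 50)), snr_db=np.inf)
        cov = estimate_covariance(rec, loading_fraction=0.05)
        np.testing.assert_array_equal(cov.matrix, np.zeros((4, 4)))

    def test_zero_loading_equals_sample_covariance(self, rng):
        x = rng.normal(size=(5, 200))
        rec = SensorRecording(samples=x, snr_db=np.inf)
        cov = estimate_covariance(rec, loading_fraction=0.0)
        np.testing.assert_allclose(cov.matrix, np.cov(x), rtol=1e-12)

    def test_white_noise_diagonal_recovers_variance(self, rng):
        sigma = 2.5
        x = rng.normal(scale=sigma, size=(6, 10_000))
        cov = estimate_covariance(
            SensorRecording(samples=x, snr_db=np.inf), loading_fraction=0.0
        )
        np.testing.assert_allclose(np.diag(cov.matrix), sigma**2, rtol=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_covariance(SensorRecording(samples=np.ones((3, 1)), snr_db=np.inf))


class TestLCMV:
    def test_unit_gain_constraint_holds_for_every_dipole(self, leadfield32, grid20mm, rng):
        sc = make_scenario("multi_focal", 2, grid20mm, rng)
        rec = simulate_recording(
            render_source_activity(sc), leadfield32, 20.0, rng
        )
        cov = estimate_covariance(rec, loading_fraction=0.05)
        c_inv = np.linalg.inv(cov.matrix)
        gain = leadfield32.gain
        live = np.einsum("sd,sd->d", gain, gain) > 0  # silent origin excluded
        # w_i^T l_i = 1 by construction
        ci_l = c_inv @ gain[:, live]
        denom = np.einsum("sd,sd->d", gain[:, live], ci_l)
        w = ci_l / denom
        np.testing.assert_allclose(
            np.einsum("sd,sd->d", w, gain[:, live]), 1.0, atol=1e-8
        )
        sol = solve_lcmv(leadfield32, cov, rec)
        assert sol.amplitudes.shape == (grid20mm.count, rec.n_samples)

    def test_output_power_peaks_at_true_dipole(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, 40.0, rng)
        cov = estimate_covariance(rec, loading_fraction=0.01)
        sol = solve_lcmv(leadfield32, cov, rec)
        power = np.einsum("dt,dt->d", sol.amplitudes, sol.amplitudes)
        # exclude the silent origin column (undefined beamformer output)
        silent = np.einsum("sd,sd->d", leadfield32.gain, leadfield32.gain) == 0
        power[silent] = 0.0
        assert np.argmax(power) == sc.active_indices[0]

    def test_filter_matches_constrained_qp_oracle(self, rng):
        """w_i solves min w^T C w s.t. w^T l_i = 1 (dense QP via SLSQP)."""
        lf = _toy_leadfield(6, 4, rng)
        noise = rng.normal(size=(6, 500))
        rec = SensorRecording(samples=noise, snr_db=np.inf)
        cov = estimate_covariance(rec, loading_fraction=0.1)
        c = cov.matrix
        c_inv = np.linalg.inv(c)
        for i in range(4):
            l_i = lf.gain[:, i]
            w_closed = c_inv @ l_i / (l_i @ c_inv @ l_i)
            res = minimize(
                lambda w: w @ c @ w,
                x0=l_i / (l_i @ l_i),
                jac=lambda w: 2 * c @ w,
                constraints={"type": "eq", "fun": lambda w: w @ l_i - 1.0},
                method="SLSQP",
                options={"ftol": 1e-16, "maxiter": 500},
            )
            np.testing.assert_allclose(res.x, w_closed, atol=1e-6)

    def test_singular_covariance_advises_loading(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, np.inf)
        cov = estimate_covariance(rec, loading_fraction=0.0)  # rank 1
        with pytest.raises(NumericalConditioningError, match="loading"):
            solve_lcmv(leadfield32, cov, rec)


class TestMNE:
    def test_large_lambda_shrinks_to_zero(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, np.inf)
        scale = float(np.sum(leadfield32.gain**2))
        small = solve_mne(leadfield32, rec, lam=1e-6 * scale)
        large = solve_mne(leadfield32, rec, lam=1e8 * scale)
        assert np.abs(large.amplitudes).max() < 1e-8 * np.abs(small.amplitudes).max()

    def test_square_invertible_interpolates_exactly(self, rng):
        lf = _toy_leadfield(4, 4, rng)
        m = rng.normal(size=(4, 30))
        rec = SensorRecording(samples=m, snr_db=np.inf)
        sol = solve_mne(lf, rec, lam=0.0)
        np.testing.assert_allclose(lf.gain @ sol.amplitudes, m, atol=1e-9)

    def test_underdetermined_matches_pseudoinverse_minimum_norm(self, rng):
        """lam -> 0 recovers the pseudoinverse solution, which has minimal
        norm among exact-fit solutions (spot-checked against null-space
        perturbations)."""
        lf = _toy_leadfield(3, 6, rng)
        m = rng.normal(size=(3, 10))
        rec = SensorRecording(samples=m, snr_db=np.inf)
        scale = np.abs(lf.gain).max() ** 2
        sol = solve_mne(lf, rec, lam=1e-12 * scale)
        q_pinv = np.linalg.pinv(lf.gain) @ m
        np.testing.assert_allclose(sol.amplitudes, q_pinv, atol=1e-8)
        # any exact-fit alternative (pinv + null-space component) is longer
        from scipy.linalg import null_space

        ns = null_space(lf.gain)
        for _ in range(10):
            alt = q_pinv + ns @ rng.normal(size=(ns.shape[1], m.shape[1]))
            assert np.linalg.norm(alt) > np.linalg.norm(q_pinv)

    def test_lambda_from_recorded_snr(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, 10.0, rng)
        sol = solve_mne(leadfield32, rec)
        gain = leadfield32.gain
        expected = np.sum(gain * gain) / (gain.shape[0] * 10.0)
        assert sol.hyperparameters["lambda"] == pytest.approx(expected)


class TestELORETA:
    def test_exact_localization_for_grid_aligned_dipole(self, leadfield32, grid20mm, rng):
        """Noiseless single grid dipoles localize exactly, shallow or deep."""
        radii = np.linalg.norm(grid20mm.positions, axis=1)
        deep = int(np.argsort(radii)[1])  # deepest off-origin dipole
        shallow = int(np.argmax(radii))
        for idx in (deep, shallow):
            act = np.zeros((grid20mm.count, 100))
            act[idx] = np.sin(np.linspace(0, 7, 100))
            rec = simulate_recording(SourceActivity(act), leadfield32, np.inf)
            sol = solve_eloreta(leadfield32, rec)
            power = np.einsum("dt,dt->d", sol.amplitudes, sol.amplitudes)
            assert int(np.argmax(power)) == idx

    def test_converged_weights_positive_and_stationary(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, 20.0, rng)
        sol = solve_eloreta(leadfield32, rec, tol=1e-8)
        assert sol.converged
        # re-run with one extra iteration budget: same fixed point
        sol2 = solve_eloreta(leadfield32, rec, tol=1e-8, max_iter=sol.n_iter + 1)
        np.testing.assert_allclose(sol.amplitudes, sol2.amplitudes, rtol=1e-6)

    def test_nonconvergence_flagged_not_raised(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, 20.0, rng)
        sol = solve_eloreta(leadfield32, rec, tol=1e-15, max_iter=2)
        assert not sol.converged and sol.n_iter == 2


class TestRVScan:
    def test_zero_residual_at_true_dipole_noiseless(self, leadfield32, grid20mm, rng):
        sc = make_scenario("single_focal", 1, grid20mm, rng)
        rec = simulate_recording(render_source_activity(sc), leadfield32, np.inf)
        sol = solve_rv_scan(leadfield32, rec)
        idx = sc.active_indices[0]
        assert sol.scores[idx] < 1e-10
        assert int(np.argmin(sol.scores)) == idx

    def test_scores_bounded_in_unit_interval(self, leadfield32, grid20mm, rng):
        sc = make_scenario("extended", 1, grid20mm, rng,
                           extended_volume_range=(14, 44))
        rec = simulate_recording(render_source_activity(sc), leadfield32, 5.0, rng)
        sol = solve_rv_scan(leadfield32, rec)
        assert np.all(sol.scores >= 0.0) and np.all(sol.scores <= 1.0)

    def test_matches_generic_least_squares_oracle(self, rng):
        lf = _toy_leadfield(5, 4, rng)
        m = rng.normal(size=(5, 40))
        rec = SensorRecording(samples=m, snr_db=np.inf)
        sol = solve_rv_scan(lf, rec)
        for i in range(4):
            l_i = lf.gain[:, [i]]
            q, *_ = np.linalg.lstsq(l_i, m, rcond=None)
            resid = np.linalg.norm(m - l_i @ q) ** 2 / np.linalg.norm(m) ** 2
            assert sol.scores[i] == pytest.approx(resid, abs=1e-10)
            np.testing.assert_allclose(sol.amplitudes[i], q[0], rtol=1e-10)

    def test_silent_column_scored_one(self, helmet32):
        from meginverse import build_source_grid, assemble_leadfield

        grid = build_source_grid(radius=0.05, spacing=0.03)  # includes origin
        lf = assemble_leadfield(helmet32, grid)
        silent = np.flatnonzero(np.einsum("sd,sd->d", lf.gain, lf.gain) == 0)
        assert silent.size >= 1
        m = lf.gain @ np.ones((grid.count, 10))
        sol = solve_rv_scan(lf, SensorRecording(samples=m, snr_db=np.inf))
        assert np.all(sol.scores[silent] == 1.0)


def test_solvers_are_deterministic(leadfield32, grid20mm, rng):
    sc = make_scenario("multi_focal", 2, grid20mm, rng)
    rec = simulate_recording(render_source_activity(sc), leadfield32, 15.0, rng)
    cov = estimate_covariance(rec)
    for solve in (
        lambda: solve_lcmv(leadfield32, cov, rec).amplitudes,
        lambda: solve_mne(leadfield32, rec).amplitudes,
        lambda: solve_eloreta(leadfield32, rec).amplitudes,
        lambda: solve_rv_scan(leadfield32, rec).amplitudes,
    ):
        np.testing.assert_array_equal(solve(), solve())
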