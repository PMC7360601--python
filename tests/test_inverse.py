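"""Levenberg-Marquardt core and sequential per-interval parameter estimation."""

import numpy as np
import pytest
import scipy.optimize

from spherofit.forward import (
    BiophysicalParams,
    CellularityField,
    SolverConfig,
    simulate_interval,
)
from spherofit.inverse import (
    FitConfig,
    IntervalProblem,
    ObservationPair,
    fit_growth_params,
    fit_interval,
    fit_timecourse,
    fit_traction,
    levenberg_marquardt,
    results_to_frame,
)

from conftest import TRUTH, radial_cellularity


class TestLevenbergMarquardt:
    @staticmethod
    def _expfit_residual(x, t, y):
        return x[0] * np.exp(x[1] * t) - y

    def test_agrees_with_scipy_on_exponential_fit(self):
        """Independent cross-check: same minimizer as scipy's trust-region
        least squares on a standard curve-fitting problem."""
        rng = np.random.default_rng(5)
        t = np.linspace(0, 4, 40)
        y = 2.5 * np.exp(-0.7 * t) + rng.normal(0, 0.01, t.size)
        x0 = np.array([1.0, -0.2])
        mine = levenberg_marquardt(
            lambda x: self._expfit_residual(x, t, y), x0,
            abs_cost_tol=0.0, rel_cost_tol=1e-12,
        )
        ref = scipy.optimize.least_squares(
            self._expfit_residual, x0, args=(t, y), method="trf", xtol=1e-14
        )
        assert np.allclose(mine.x, ref.x, rtol=1e-4)

    def test_accepted_steps_never_increase_cost(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 4, 30)
        y = 1.5 * np.exp(0.3 * t) + rng.normal(0, 0.05, t.size)
        res = levenberg_marquardt(
            lambda x: self._expfit_residual(x, t, y), [0.5, 0.0],
            abs_cost_tol=0.0, rel_cost_tol=1e-10,
        )
        hist = np.asarray(res.cost_history)
        assert np.all(np.diff(hist) <= 0)

    def test_reports_exactly_one_stopping_reason(self):
        res = levenberg_marquardt(lambda x: np.array([x[0] - 1.0]), [5.0])
        assert res.convergence_reason in (
            "absolute_objective", "relative_objective",
            "max_iterations", "max_function_evals",
        )

    def test_respects_bounds(self):
        res = levenberg_marquardt(
            lambda x: np.array([x[0] - 10.0]), [0.5], bounds=([0.0], [1.0]),
            abs_cost_tol=0.0,
        )
        assert 0.0 <= res.x[0] <= 1.0
        assert res.x[0] == pytest.approx(1.0)

    def test_evaluation_budget_honored(self):
        calls = []

        def residual(x):
            calls.append(1)
            return np.array([np.sin(x[0]) + 2.0])  # no zero exists

        levenberg_marquardt(residual, [0.1], max_function_evals=30, abs_cost_tol=0.0,
                            rel_cost_tol=1e-16)
        assert len(calls) <= 31


class TestResiduals:
    def test_self_consistency_residuals_vanish(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        r_cell = problem.cellularity_residual(TRUTH["D0"], TRUTH["k"], TRUTH["lam"])
        r_disp = problem.displacement_residual(TRUTH["lam"], TRUTH["D0"], TRUTH["k"])
        assert np.allclose(r_cell, 0.0, atol=1e-12)
        assert np.allclose(r_disp, 0.0, atol=1e-12)
        assert r_cell.shape == (mesh500.n_nodes,)
        assert r_disp.shape == (2 * mesh500.n_nodes,)

    def test_objective_grows_away_from_generating_k(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())

        def cell_obj(k):
            r = problem.cellularity_residual(TRUTH["D0"], k, TRUTH["lam"])
            return float(r @ r)

        assert cell_obj(1.5 * TRUTH["k"]) > cell_obj(TRUTH["k"])
        assert cell_obj(0.5 * TRUTH["k"]) > cell_obj(TRUTH["k"])

    def test_displacement_objective_has_single_bracketed_minimum(
        self, mesh500, spheroid_state, noiseless_interval
    ):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        lams = np.linspace(-3200, 0, 9)
        objs = [
            float(np.sum(problem.displacement_residual(l, TRUTH["D0"], TRUTH["k"]) ** 2))
            for l in lams
        ]
        i_min = int(np.argmin(objs))
        assert lams[i_min] == pytest.approx(TRUTH["lam"], rel=0.15)
        # strictly decreasing then increasing around the minimum
        assert all(a > b for a, b in zip(objs[:i_min], objs[1 : i_min + 1]))
        assert all(a < b for a, b in zip(objs[i_min:-1], objs[i_min + 1 :]))


class TestGrowthFit:
    def test_noiseless_recovery_from_doubled_init(self, mesh500, spheroid_state):
        n0, material = spheroid_state
        gen = BiophysicalParams(D0=TRUTH["D0"], k=TRUTH["k"], lam=0.0, interval=(24, 36))
        sim = simulate_interval(n0, gen, material, mesh500, SolverConfig())
        obs = ObservationPair(n0, sim.n_end, sim.displacement)
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        (d0, k), lm = fit_growth_params(problem, 0.0, init=(2 * TRUTH["D0"], 2 * TRUTH["k"]))
        assert d0 == pytest.approx(TRUTH["D0"], rel=0.01)
        assert k == pytest.approx(TRUTH["k"], rel=0.01)

    def test_init_at_truth_stops_immediately(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        (_, _), lm = fit_growth_params(problem, TRUTH["lam"], init=(TRUTH["D0"], TRUTH["k"]))
        assert lm.convergence_reason in ("absolute_objective", "relative_objective")
        assert lm.n_iterations <= 2

    def test_uniform_cellularity_leaves_d0_unidentifiable(self, mesh500, spheroid_state):
        """With no spatial structure, diffusion does nothing: the objective
        gradient with respect to D0 is numerically zero."""
        _, material = spheroid_state
        n_uniform = CellularityField(np.full(mesh500.n_nodes, 0.2), 24.0)
        gen = BiophysicalParams(D0=TRUTH["D0"], k=TRUTH["k"], lam=0.0, interval=(24, 36))
        sim = simulate_interval(n_uniform, gen, material, mesh500, SolverConfig())
        obs = ObservationPair(n_uniform, sim.n_end, sim.displacement)
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())

        def obj(d0):
            r = problem.cellularity_residual(d0, 2 * TRUTH["k"], 0.0)
            return float(r @ r)

        grad = (obj(220.0) - obj(200.0)) / 20.0
        assert abs(grad) < 1e-12


class TestTractionFit:
    def test_noiseless_recovery_from_zero_init(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        lam, _ = fit_traction(problem, TRUTH["D0"], TRUTH["k"], init_lambda=0.0)
        assert lam == pytest.approx(TRUTH["lam"], rel=0.01)

    def test_zero_deformation_yields_zero_lambda(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        obs0 = ObservationPair(obs.n_obs_start, obs.n_obs_end, np.zeros((mesh500.n_nodes, 2)))
        problem = IntervalProblem(obs0, mesh500, material, SolverConfig())
        lam, _ = fit_traction(problem, TRUTH["D0"], TRUTH["k"], init_lambda=100.0)
        assert abs(lam) < 1.0  # |λ̂| far below the physical scale of ~10²-10³

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_recovered_sign_matches_generating_sign(self, mesh500, spheroid_state, sign):
        n0, material = spheroid_state
        gen = BiophysicalParams(D0=300.0, k=0.01, lam=sign * 800.0, interval=(24, 36))
        sim = simulate_interval(n0, gen, material, mesh500, SolverConfig())
        obs = ObservationPair(n0, sim.n_end, sim.displacement)
        problem = IntervalProblem(obs, mesh500, material, SolverConfig())
        lam, _ = fit_traction(problem, 300.0, 0.01, init_lambda=0.0)
        assert np.sign(lam) == sign
        assert lam == pytest.approx(sign * 800.0, rel=0.01)


class TestSequentialFit:
    def test_full_triplet_recovery_noiseless(self, noiseless_fit):
        p = noiseless_fit.params
        assert p.D0 == pytest.approx(TRUTH["D0"], rel=0.01)
        assert p.k == pytest.approx(TRUTH["k"], rel=0.01)
        assert p.lam == pytest.approx(TRUTH["lam"], rel=0.01)
        assert noiseless_fit.outer_converged

    def test_outer_loop_bookkeeping(self, noiseless_fit):
        assert noiseless_fit.outer_iterations >= 1
        assert noiseless_fit.outer_passes >= noiseless_fit.outer_iterations
        assert noiseless_fit.convergence_reason in (
            "absolute_objective", "relative_objective",
            "max_iterations", "max_function_evals",
        )
        assert len(noiseless_fit.lm_reasons) == 2 * noiseless_fit.outer_passes

    def test_zero_lambda_observations_converge_in_one_update(self, mesh500, spheroid_state):
        n0, material = spheroid_state
        gen = BiophysicalParams(D0=TRUTH["D0"], k=TRUTH["k"], lam=0.0, interval=(24, 36))
        sim = simulate_interval(n0, gen, material, mesh500, SolverConfig())
        obs = ObservationPair(n0, sim.n_end, sim.displacement)
        fit = fit_interval(
            obs, mesh500, material, SolverConfig(),
            FitConfig(init_d0=2 * TRUTH["D0"], init_k=2 * TRUTH["k"]),
        )
        assert fit.outer_iterations <= 2
        assert abs(fit.params.lam) < 1.0

    def test_noisy_recovery_within_ten_percent(self, mesh500, spheroid_state, noiseless_interval):
        """1% additive Gaussian observation noise, three seeded replicates."""
        _, material = spheroid_state
        obs, _ = noiseless_interval
        scale_u = np.abs(obs.deformation_obs).max()
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n_noisy = np.clip(
                obs.n_obs_end.values + rng.normal(0, 0.01, mesh500.n_nodes), 0.0, 1.0
            )
            u_noisy = obs.deformation_obs + rng.normal(0, 0.01 * scale_u, (mesh500.n_nodes, 2))
            noisy = ObservationPair(
                obs.n_obs_start,
                CellularityField(n_noisy, obs.n_obs_end.time_stamp),
                u_noisy,
            )
            fit = fit_interval(
                noisy, mesh500, material, SolverConfig(),
                FitConfig(init_d0=2 * TRUTH["D0"], init_k=2 * TRUTH["k"]),
            )
            assert fit.params.D0 == pytest.approx(TRUTH["D0"], rel=0.10)
            assert fit.params.k == pytest.approx(TRUTH["k"], rel=0.10)
            assert fit.params.lam == pytest.approx(TRUTH["lam"], rel=0.10)


class TestTimecourse:
    def test_constant_parameters_give_flat_trajectories(self, mesh500, spheroid_state):
        n0, material = spheroid_state
        gen = dict(D0=300.0, k=0.01, lam=-800.0)
        fields, defs = [n0], []
        for i in range(2):
            params = BiophysicalParams(**gen, interval=(24 + 12 * i, 36 + 12 * i))
            sim = simulate_interval(fields[-1], params, material, mesh500, SolverConfig())
            fields.append(sim.n_end)
            defs.append(sim.displacement)
        obs = [ObservationPair(fields[i], fields[i + 1], defs[i]) for i in range(2)]
        results = fit_timecourse(obs, mesh500, material, SolverConfig(),
                                 FitConfig(init_d0=500.0, init_k=0.02))
        frame = results_to_frame(results)
        assert np.allclose(frame.D0_um2_per_h, 300.0, rtol=0.01)
        assert np.allclose(frame.k_per_h, 0.01, rtol=0.01)
        assert np.allclose(frame["lambda"], -800.0, rtol=0.01)
        # second interval seeds from the first: it should start near truth
        assert results[1].inner_function_evals <= results[0].inner_function_evals

    def test_failures_are_isolated(self, mesh500, spheroid_state, noiseless_interval):
        _, material = spheroid_state
        obs, _ = noiseless_interval
        bad = ObservationPair(
            CellularityField(obs.n_obs_start.values, 36.0),
            CellularityField(obs.n_obs_end.values, 48.0),
            obs.deformation_obs,
        )
        # mismatched mesh: different node count → isolated flagged failure
        from spherofit.mesh import build_mesh

        small_mesh = build_mesh((500, 500), 80.0)
        results = fit_timecourse([obs], small_mesh, material, SolverConfig(), FitConfig())
        assert len(results) == 1
        assert results[0].convergence_reason.startswith("error")
        assert np.isnan(results[0].params.k)
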