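"""Sequential inverse estimation of per-interval biophysical parameters.

Between each pair of consecutive imaging time points the forward model is fit
to two observations: the normalized cellularity map at the end of the interval
and the bead-derived deformation field over the interval.  Because the
cellularity data constrain (D₀, k) strongly and the deformation data constrain
λ, the fit is *sequential*: a Levenberg–Marquardt (LM) least-squares pass over
(D₀, k) against the cellularity objective with λ held fixed, then an LM pass
over λ against the displacement objective with (D₀, k) fixed, alternated until
the triplet stabilizes.  On noiseless synthetic data the outer loop settles in
two passes.

The LM stopping rules are: (a) absolute objective below 1e-4, (b) relative
objective change between accepted iterations below 1e-2, (c) 500 iterations,
(d) 1000 function evaluations — whichever fires first; in practice (b) is the
typical one on noisy data and (a) on noiseless phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import (
    BiophysicalParams,
    CellularityField,
    ElasticitySystem,
    MaterialMap,
    SolverConfig,
    StabilityError,
    SolverError,
    simulate_interval,
)
from .mesh import TriMesh

CONVERGENCE_REASONS = (
    "absolute_objective",
    "relative_objective",
    "max_iterations",
    "max_function_evals",
)


# ----------------------------------------------------------------------------
# Levenberg-Marquardt core


@dataclass
class LMResult:
    x: np.ndarray
    cost: float
    n_iterations: int
    n_function_evals: int
    convergence_reason: str
    cost_history: list = field(default_factory=list)


def levenberg_marquardt(
    residual_fn,
    x0,
    bounds=None,
    abs_cost_tol: float = 1e-4,
    rel_cost_tol: float = 1e-2,
    max_iterations: int = 500,
    max_function_evals: int = 1000,
    fd_rel_step: float = 1e-4,
    x_scale=None,
) -> LMResult:
    """Damped least-squares minimization of ``sum(residual_fn(x)**2)``.

    Classic Marquardt damping on the normal equations with a forward-difference
    Jacobian; trial points are clipped to ``bounds``.  A residual function may
    return None (or raise a solver instability) at an infeasible point, which
    is treated as a rejected step.  Accepted steps never increase the cost.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    nparam = x.size
    if bounds is None:
        lo = np.full(nparam, -np.inf)
        hi = np.full(nparam, np.inf)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    x = np.clip(x, lo, hi)
    scale = np.ones(nparam) if x_scale is None else np.asarray(x_scale, dtype=float)

    nfev = 0

    def safe_residual(xt):
        nonlocal nfev
        nfev += 1
        try:
            r = residual_fn(xt)
        except (StabilityError, SolverError):
            return None
        if r is None or not np.all(np.isfinite(r)):
            return None
        return np.asarray(r, dtype=float)

    r = safe_residual(x)
    if r is None:
        raise ValueError(f"residual function infeasible at the initial point {x}")
    cost = float(r @ r)
    history = [cost]
    mu = None
    nu = 2.0
    reason = "max_iterations"

    if cost < abs_cost_tol:
        return LMResult(x, cost, 0, nfev, "absolute_objective", history)

    for iteration in range(1, max_iterations + 1):
        # forward-difference Jacobian
        jac = np.empty((r.size, nparam))
        feasible = True
        for j in range(nparam):
            h = fd_rel_step * max(abs(x[j]), scale[j])
            xj = x.copy()
            xj[j] = min(x[j] + h, hi[j]) if x[j] + h <= hi[j] else x[j] - h
            h_eff = xj[j] - x[j]
            rj = safe_residual(xj)
            if rj is None or h_eff == 0.0:
                feasible = False
                break
            jac[:, j] = (rj - r) / h_eff
        if not feasible or nfev >= max_function_evals:
            reason = "max_function_evals" if nfev >= max_function_evals else reason
            break

        jtj = jac.T @ jac
        jtr = jac.T @ r
        # Marquardt scaling: damp relative to the curvature of each direction,
        # which keeps the step well-conditioned across parameter magnitudes.
        damp = np.diag(np.maximum(np.diag(jtj), 1e-30))
        if mu is None:
            mu = 1e-3

        accepted = False
        while not accepted:
            try:
                step = np.linalg.solve(jtj + mu * damp, -jtr)
            except np.linalg.LinAlgError:
                step = None
            if step is not None:
                x_trial = np.clip(x + step, lo, hi)
                r_trial = safe_residual(x_trial)
            else:
                r_trial = None
            if r_trial is not None and float(r_trial @ r_trial) < cost:
                new_cost = float(r_trial @ r_trial)
                rel_drop = (cost - new_cost) / max(cost, 1e-300)
                x, r, cost = x_trial, r_trial, new_cost
                history.append(cost)
                mu = max(mu / 3.0, 1e-30)
                nu = 2.0
                accepted = True
                if cost < abs_cost_tol:
                    return LMResult(x, cost, iteration, nfev, "absolute_objective", history)
                if rel_drop < rel_cost_tol:
                    return LMResult(x, cost, iteration, nfev, "relative_objective", history)
            else:
                mu *= nu
                nu *= 2.0
                if nfev >= max_function_evals:
                    return LMResult(x, cost, iteration, nfev, "max_function_evals", history)
                if mu > 1e30:  # no downhill direction left: stationary point
                    return LMResult(x, cost, iteration, nfev, "relative_objective", history)
            if nfev >= max_function_evals:
                return LMResult(x, cost, iteration, nfev, "max_function_evals", history)

    return LMResult(x, cost, max_iterations, nfev, reason, history)


# ----------------------------------------------------------------------------
# observation container and fitting problem


@dataclass(frozen=True)
class ObservationPair:
    """Observed cellularity at two consecutive time points plus the interval
    deformation field, all sampled at the mesh nodes.

    ``displacement_operator``, when present, is the linear measurement
    operator (n_nodes × n_nodes) of the bead observation process (sampling at
    bead positions followed by smooth-field reconstruction); the displacement
    objective then compares the *measured* model displacement with the
    observation so reconstruction smoothing cancels instead of biasing λ.
    """

    n_obs_start: CellularityField
    n_obs_end: CellularityField
    deformation_obs: np.ndarray  # (n_nodes, 2), µm
    displacement_operator: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_obs_end.time_stamp <= self.n_obs_start.time_stamp:
            raise ValueError("observation end time must exceed start time")
        if self.n_obs_start.values.shape != self.n_obs_end.values.shape:
            raise ValueError("observation fields live on different meshes")
        u = np.asarray(self.deformation_obs, dtype=float)
        object.__setattr__(self, "deformation_obs", u)
        if u.shape != (self.n_obs_start.values.size, 2):
            raise ValueError(
                f"deformation shape {u.shape} does not match {self.n_obs_start.values.size} nodes"
            )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.n_obs_start.time_stamp, self.n_obs_end.time_stamp)


@dataclass(frozen=True)
class FitConfig:
    """Initialization, bounds and loop controls for the sequential fit."""

    init_d0: float = 200.0  # µm²/h
    init_k: float = 5e-3  # 1/h
    init_lambda: float = 0.0  # the "arbitrary assigned" first-pass traction
    gamma: float = 2.5e-3  # 1/Pa, fixed (not fitted)
    d0_bounds: tuple[float, float] = (0.0, 1e4)
    k_bounds: tuple[float, float] = (-1.0, 1.0)
    lambda_bounds: tuple[float, float] = (-np.inf, np.inf)
    outer_tol: float = 1e-2  # max relative triplet change between outer passes
    outer_max: int = 10
    abs_cost_tol: float = 1e-4
    rel_cost_tol: float = 1e-2
    max_iterations: int = 500
    max_function_evals: int = 1000
    # characteristic magnitudes used for finite-difference steps near zero
    d0_scale: float = 100.0
    k_scale: float = 1e-2
    lambda_scale: float = 100.0


@dataclass
class FitResult:
    """Fitted triplet with objective values and loop bookkeeping.

    ``outer_iterations`` counts the sequential passes that *updated* the
    parameter triplet (relative change ≥ the outer tolerance), i.e. the
    iteration at which the final parameter values were attained;
    ``outer_passes`` additionally includes the terminal pass that confirmed
    convergence without changing the triplet.
    """

    params: BiophysicalParams
    objective_cellularity: float
    objective_displacement: float
    outer_iterations: int
    outer_passes: int
    outer_converged: bool
    convergence_reason: str  # last inner LM stopping reason
    inner_iterations: int  # summed over LM passes
    inner_function_evals: int
    lm_reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "interval_end_h": self.params.interval[1],
            "D0_um2_per_h": self.params.D0,
            "k_per_h": self.params.k,
            "lambda": self.params.lam,
            "obj_cell": self.objective_cellularity,
            "obj_disp": self.objective_displacement,
            "outer_iters": self.outer_iterations,
            "reason": self.convergence_reason,
        }


class IntervalProblem:
    """Bundles the mesh, material and solver settings for one interval fit.

    Holds a prefactorized elasticity system so each forward evaluation inside
    the LM loops costs only explicit time stepping and back-substitutions.
    """

    def __init__(
        self,
        obs: ObservationPair,
        mesh: TriMesh,
        material: MaterialMap,
        solver_config: SolverConfig | None = None,
        fit_config: FitConfig | None = None,
    ):
        self.obs = obs
        self.mesh = mesh
        self.material = material
        self.fit_config = fit_config or FitConfig()
        interval_hours = obs.interval[1] - obs.interval[0]
        self.solver_config = solver_config or SolverConfig(interval_hours=interval_hours)
        if abs(self.solver_config.interval_hours - interval_hours) > 1e-9:
            raise ValueError("solver config interval does not match observation spacing")
        if obs.n_obs_start.values.size != mesh.n_nodes:
            raise ValueError("observation fields do not live on the given mesh")
        self.elasticity = ElasticitySystem(mesh, material)

    def simulate(self, d0: float, k: float, lam: float):
        params = BiophysicalParams(
            D0=d0, k=k, lam=lam, gamma=self.fit_config.gamma, interval=self.obs.interval
        )
        return simulate_interval(
            self.obs.n_obs_start, params, self.material, self.mesh,
            self.solver_config, elasticity=self.elasticity,
        )

    def cellularity_residual(self, d0: float, k: float, lam: float) -> np.ndarray:
        """Per-node residual N_model(t_end) − N_obs(t_end)."""
        res = self.simulate(d0, k, lam)
        return res.n_end.values - self.obs.n_obs_end.values

    def displacement_residual(self, lam: float, d0: float, k: float) -> np.ndarray:
        """Stacked per-node X and Y residuals u_model − u_obs (equal weights).

        If the observation carries a measurement operator, the model
        displacement is passed through it before comparison.
        """
        res = self.simulate(d0, k, lam)
        u_model = res.displacement
        if self.obs.displacement_operator is not None:
            u_model = self.obs.displacement_operator @ u_model
        return (u_model - self.obs.deformation_obs).ravel()


def fit_growth_params(
    problem: IntervalProblem, lambda_fixed: float, init: tuple[float, float] | None = None
) -> tuple[tuple[float, float], LMResult]:
    """LM fit of (D₀, k) against the cellularity objective, λ held fixed."""
    cfg = problem.fit_config
    if init is None:
        init = (cfg.init_d0, cfg.init_k)
    lm = levenberg_marquardt(
        lambda x: problem.cellularity_residual(x[0], x[1], lambda_fixed),
        np.asarray(init, dtype=float),
        bounds=(
            [cfg.d0_bounds[0], cfg.k_bounds[0]],
            [cfg.d0_bounds[1], cfg.k_bounds[1]],
        ),
        abs_cost_tol=cfg.abs_cost_tol,
        rel_cost_tol=cfg.rel_cost_tol,
        max_iterations=cfg.max_iterations,
        max_function_evals=cfg.max_function_evals,
        x_scale=[cfg.d0_scale, cfg.k_scale],
    )
    return (float(lm.x[0]), float(lm.x[1])), lm


def fit_traction(
    problem: IntervalProblem, d0_fixed: float, k_fixed: float, init_lambda: float | None = None
) -> tuple[float, LMResult]:
    """LM fit of λ against the displacement objective, (D₀, k) held fixed."""
    cfg = problem.fit_config
    if init_lambda is None:
        init_lambda = cfg.init_lambda
    lm = levenberg_marquardt(
        lambda x: problem.displacement_residual(x[0], d0_fixed, k_fixed),
        np.asarray([init_lambda], dtype=float),
        bounds=([cfg.lambda_bounds[0]], [cfg.lambda_bounds[1]]),
        abs_cost_tol=cfg.abs_cost_tol,
        rel_cost_tol=cfg.rel_cost_tol,
        max_iterations=cfg.max_iterations,
        max_function_evals=cfg.max_function_evals,
        x_scale=[cfg.lambda_scale],
    )
    return float(lm.x[0]), lm


def _rel_change(new: np.ndarray, old: np.ndarray, scales: np.ndarray) -> float:
    return float(np.max(np.abs(new - old) / np.maximum(np.abs(old), scales * 1e-3)))


def fit_interval(
    obs: ObservationPair,
    mesh: TriMesh,
    material: MaterialMap,
    solver_config: SolverConfig | None = None,
    fit_config: FitConfig | None = None,
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Sequential (D₀, k) ↔ λ estimation for one imaging interval.

    Alternates growth and traction LM passes; the first growth pass uses the
    configured arbitrary λ (default 0, i.e. an uncoupled reaction-diffusion
    fit), and the loop stops once the maximum relative change of the triplet
    between outer passes drops below ``outer_tol`` (or the pass cap is hit,
    in which case the result is flagged, not raised).
    """
    problem = IntervalProblem(obs, mesh, material, solver_config, fit_config)
    cfg = problem.fit_config
    scales = np.array([cfg.d0_scale, cfg.k_scale, cfg.lambda_scale])
    if init is None:
        init = (cfg.init_d0, cfg.init_k, cfg.init_lambda)
    d0, k = float(init[0]), float(init[1])
    lam = float(init[2]) if len(init) > 2 else cfg.init_lambda

    triplet = np.array([d0, k, lam])
    reasons: list[str] = []
    total_iters = total_nfev = 0
    converged = False
    outer = 0
    n_updates = 0
    lm_growth = lm_tract = None
    for outer in range(1, cfg.outer_max + 1):
        (d0, k), lm_growth = fit_growth_params(problem, lam, init=(d0, k))
        lam, lm_tract = fit_traction(problem, d0, k, init_lambda=lam)
        reasons += [lm_growth.convergence_reason, lm_tract.convergence_reason]
        total_iters += lm_growth.n_iterations + lm_tract.n_iterations
        total_nfev += lm_growth.n_function_evals + lm_tract.n_function_evals
        new_triplet = np.array([d0, k, lam])
        change = _rel_change(new_triplet, triplet, scales)
        triplet = new_triplet
        if change < cfg.outer_tol:
            converged = True
            break
        n_updates += 1

    params = BiophysicalParams(
        D0=triplet[0], k=triplet[1], lam=triplet[2], gamma=cfg.gamma, interval=obs.interval
    )
    return FitResult(
        params=params,
        objective_cellularity=lm_growth.cost,
        objective_displacement=lm_tract.cost,
        outer_iterations=max(1, n_updates),
        outer_passes=outer,
        outer_converged=converged,
        convergence_reason=lm_tract.convergence_reason,
        inner_iterations=total_iters,
        inner_function_evals=total_nfev,
        lm_reasons=reasons,
    )


def fit_timecourse(
    observations: list[ObservationPair],
    mesh: TriMesh,
    material: MaterialMap,
    solver_config: SolverConfig | None = None,
    fit_config: FitConfig | None = None,
) -> list[FitResult]:
    """Independent per-interval fits over a full time course.

    Parameters are piecewise constant per interval; each interval's
    initialization is seeded from the previous interval's estimate (the first
    interval starts from the configured defaults).  A failure in one interval
    is isolated: the result carries NaN parameters and the error message, and
    later intervals fall back to default initialization.
    """
    cfg = fit_config or FitConfig()
    results: list[FitResult] = []
    init = (cfg.init_d0, cfg.init_k, cfg.init_lambda)
    for obs in observations:
        try:
            res = fit_interval(obs, mesh, material, solver_config, cfg, init=init)
        except (StabilityError, SolverError, ValueError) as exc:
            res = FitResult(
                params=BiophysicalParams(
                    D0=0.0, k=np.nan, lam=np.nan, gamma=cfg.gamma, interval=obs.interval
                ),
                objective_cellularity=np.nan,
                objective_displacement=np.nan,
                outer_iterations=1,
                outer_passes=0,
                outer_converged=False,
                convergence_reason=f"error: {exc}",
                inner_iterations=0,
                inner_function_evals=0,
            )
            init = (cfg.init_d0, cfg.init_k, cfg.init_lambda)
            results.append(res)
            continue
        init = (res.params.D0, res.params.k, res.params.lam)
        results.append(res)
    return results


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Tabulate fitted trajectories (one row per interval)."""
    return pd.DataFrame.from_records([r.to_dict() for r in results])


def save_results(results: list[FitResult], csv_path, json_path=None) -> None:
    results_to_frame(results).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = []
        for r in results:
            d = r.to_dict()
            d.update(
                outer_converged=r.outer_converged,
                inner_iterations=r.inner_iterations,
                inner_function_evals=r.inner_function_evals,
                lm_reasons=r.lm_reasons,
                gamma=r.params.gamma,
                interval=list(r.params.interval),
            )
            payload.append(d)
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
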