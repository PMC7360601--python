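"""Coupled mechano-reaction-diffusion forward model of spheroid growth.

The model tracks a normalized cell density N(x, t) ∈ [0, θ] on a fixed
triangular mesh.  Three coupled relations govern an imaging interval:

* logistic reaction-diffusion,  ∂N/∂t = ∇·(D ∇N) + k N (1 − N/θ);
* stress attenuation of motility,  D = D₀ exp(−γ σ_VM), with σ_VM the
  von Mises stress;
* quasi-static linear-elastic equilibrium of the surrounding hydrogel,
  ∇·G∇u + ∇[G/(1−2ν)](∇·u) − λ∇N = 0, forced by the cellularity gradient
  through the traction coefficient λ.

Space is discretized by Galerkin P1 finite elements (plane strain for the
mechanics); time by fully explicit forward Euler with a row-sum lumped mass
matrix.  Boundary conditions: zero displacement on the image border (the gel
is anchored far from the spheroid) and natural no-flux for N.  Within an
interval the elastic forcing uses the cellularity *change* since the interval
start, so the returned displacement field is the incremental deformation over
that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import TriMesh

THETA_DEFAULT = 1.0


class StabilityError(RuntimeError):
    """Explicit time step exceeds the diffusion stability limit."""


class SolverError(RuntimeError):
    """Mechanical equilibrium solve failed or produced non-finite values."""


@dataclass(frozen=True)
class BiophysicalParams:
    """Per-interval parameter triplet plus the mechanical coupling constant.

    D0 : global cellular diffusion coefficient, µm²/h (≥ 0).
    k : proliferation rate, 1/h (sign free; negative means net death).
    lam : traction-force coefficient, Pa per unit normalized cellularity
        (sign free; fitted values in this system are negative, i.e. the
        force acts down the cellularity gradient, pushing the gel outward).
    gamma : stress-diffusion coupling, 1/Pa (≥ 0).
    interval : (t_start, t_end) in hours.
    """

    D0: float
    k: float
    lam: float
    gamma: float = 2.5e-3
    interval: tuple[float, float] = (0.0, 12.0)

    def __post_init__(self) -> None:
        if self.D0 < 0:
            raise ValueError(f"D0 must be non-negative, got {self.D0}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if not self.interval[1] > self.interval[0]:
            raise ValueError(f"interval must have t_end > t_start, got {self.interval}")


@dataclass(frozen=True)
class CellularityField:
    """Nodal normalized cell density at one time stamp (hours)."""

    values: np.ndarray
    time_stamp: float
    theta: float = THETA_DEFAULT

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("cellularity field contains non-finite values")
        if v.min() < -1e-12 or v.max() > self.theta + 1e-12:
            raise ValueError(
                f"cellularity outside [0, {self.theta}]: min {v.min()}, max {v.max()}"
            )


@dataclass(frozen=True)
class MaterialMap:
    """Per-element linear-elastic material: Young's modulus and Poisson ratio.

    The derived shear modulus G = E / (2 (1 + ν)) is exposed per element.
    """

    youngs_modulus: np.ndarray  # Pa, per element
    poissons_ratio: float = 0.45

    def __post_init__(self) -> None:
        e = np.asarray(self.youngs_modulus, dtype=float)
        object.__setattr__(self, "youngs_modulus", e)
        if np.any(e <= 0):
            raise ValueError("Young's modulus must be positive everywhere")
        if not 0 < self.poissons_ratio < 0.5:
            raise ValueError(f"Poisson ratio must be in (0, 0.5), got {self.poissons_ratio}")

    @property
    def shear_modulus(self) -> np.ndarray:
        return self.youngs_modulus / (2.0 * (1.0 + self.poissons_ratio))


def uniform_material(mesh: TriMesh, youngs_pa: float = 2000.0, nu: float = 0.45) -> MaterialMap:
    """Homogeneous gel material (default 2 kPa collagen, ν = 0.45)."""
    return MaterialMap(np.full(mesh.n_triangles, float(youngs_pa)), nu)


def material_from_core(
    mesh: TriMesh,
    n_initial: np.ndarray,
    core_threshold: float = 0.5,
    youngs_ecm_pa: float = 2000.0,
    core_stiffening: float = 10.0,
    nu: float = 0.45,
) -> MaterialMap:
    """Material map with a stiffer spheroid core.

    Elements whose centroid cellularity at the initial time point exceeds
    ``core_threshold`` are assigned ``core_stiffening`` × the gel modulus
    (default an order of magnitude above 2 kPa); the map is static over time.
    """
    centroid_n = np.asarray(n_initial, float)[mesh.triangles].mean(axis=1)
    e = np.full(mesh.n_triangles, float(youngs_ecm_pa))
    e[centroid_n > core_threshold] *= core_stiffening
    return MaterialMap(e, nu)


@dataclass(frozen=True)
class MechanicalState:
    """Equilibrium solution: nodal displacement and per-element stress."""

    displacement: np.ndarray  # (n_nodes, 2), µm
    stress: np.ndarray  # (n_tri, 4): σxx, σyy, σxy, σzz in Pa
    von_mises_stress: np.ndarray  # (n_tri,), Pa


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration settings for one imaging interval."""

    dt: float = 0.125  # hours
    interval_hours: float = 12.0
    mechanics_update_every: int = 1  # Euler steps between equilibrium re-solves
    cfl_safety: float = 0.9
    theta: float = THETA_DEFAULT
    overshoot_epsilon: float = 1e-6
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        n = self.interval_hours / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"dt={self.dt} must divide interval_hours={self.interval_hours}"
            )
        if not 0 < self.cfl_safety <= 1:
            raise ValueError(f"cfl_safety must be in (0, 1], got {self.cfl_safety}")
        if self.mechanics_update_every < 1:
            raise ValueError("mechanics_update_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return round(self.interval_hours / self.dt)


# ----------------------------------------------------------------------------
# scalar relations


def von_mises(sxx, syy, sxy, szz) -> np.ndarray:
    """Von Mises (distortional) stress from plane-strain tensor components."""
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2) + 3.0 * sxy**2
    )


def effective_diffusion(d0: float, gamma: float, vm_stress: np.ndarray) -> np.ndarray:
    """Stress-attenuated diffusion D = D₀ exp(−γ σ_VM), per element."""
    if d0 < 0 or gamma < 0:
        raise ValueError("D0 and gamma must be non-negative")
    return d0 * np.exp(-gamma * np.asarray(vm_stress, float))


def cfl_limit(max_d: float, mesh: TriMesh, cfl_safety: float = 1.0) -> float:
    """Largest stable explicit step h_min² / (4 D_max), scaled by the safety factor."""
    if max_d < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if max_d == 0:
        return np.inf
    return cfl_safety * mesh.min_edge_length() ** 2 / (4.0 * max_d)


# ----------------------------------------------------------------------------
# FEM assembly


def assemble_diffusion_stiffness(mesh: TriMesh, d_per_element: np.ndarray) -> sparse.csr_matrix:
    """Stiffness K with K_ij = Σ_e D_e A_e ∇φ_i·∇φ_j (natural no-flux BCs)."""
    d = np.broadcast_to(np.asarray(d_per_element, float), (mesh.n_triangles,))
    g = mesh.shape_gradients  # (m, 3, 2)
    ke = np.einsum("e,eid,ejd->eij", d * mesh.areas, g, g)
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    k = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(mesh.n_nodes,) * 2)
    return k.tocsr()


def _plane_strain_c(e: np.ndarray, nu: float) -> np.ndarray:
    """(m, 3, 3) plane-strain constitutive matrices per element."""
    f = e / ((1 + nu) * (1 - 2 * nu))
    c = np.zeros((e.shape[0], 3, 3))
    c[:, 0, 0] = c[:, 1, 1] = f * (1 - nu)
    c[:, 0, 1] = c[:, 1, 0] = f * nu
    c[:, 2, 2] = f * (1 - 2 * nu) / 2.0
    return c


class ElasticitySystem:
    """Prefactorized plane-strain equilibrium solver on a fixed mesh.

    Zero-displacement conditions are imposed on the domain boundary; the
    reduced stiffness is LU-factorized once, so repeated solves (one per
    Euler step, and many per inverse-fit iteration) cost a back-substitution.
    """

    def __init__(self, mesh: TriMesh, material: MaterialMap):
        self.mesh = mesh
        self.material = material
        free_nodes = ~mesh.boundary_mask
        if not np.any(free_nodes):
            raise SolverError("mesh has no interior nodes; equilibrium system is trivial")
        # interleaved dof numbering: node i -> (2i, 2i+1)
        self._free_dofs = np.where(np.repeat(free_nodes, 2))[0]
        self._c = _plane_strain_c(material.youngs_modulus, material.poissons_ratio)
        self._b = self._strain_displacement()
        k = self._assemble_stiffness()
        self._lu = splu(k[np.ix_(self._free_dofs, self._free_dofs)].tocsc())

    def _strain_displacement(self) -> np.ndarray:
        """(m, 3, 6) B matrices: strain (εxx, εyy, γxy) from element dofs."""
        g = self.mesh.shape_gradients
        m = self.mesh.n_triangles
        b = np.zeros((m, 3, 6))
        for i in range(3):
            b[:, 0, 2 * i] = g[:, i, 0]
            b[:, 1, 2 * i + 1] = g[:, i, 1]
            b[:, 2, 2 * i] = g[:, i, 1]
            b[:, 2, 2 * i + 1] = g[:, i, 0]
        return b

    def _assemble_stiffness(self) -> sparse.csr_matrix:
        mesh = self.mesh
        ke = np.einsum("e,eki,ekl,elj->eij", mesh.areas, self._b, self._c, self._b)
        tri = mesh.triangles
        dofs = np.empty((mesh.n_triangles, 6), dtype=np.int64)
        dofs[:, 0::2] = 2 * tri
        dofs[:, 1::2] = 2 * tri + 1
        rows = np.repeat(dofs, 6, axis=1).ravel()
        cols = np.tile(dofs, (1, 6)).ravel()
        n = 2 * mesh.n_nodes
        return sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    def _solve_load(self, load: np.ndarray) -> np.ndarray:
        u = np.zeros(2 * self.mesh.n_nodes)
        u[self._free_dofs] = self._lu.solve(load[self._free_dofs])
        if not np.all(np.isfinite(u)):
            raise SolverError("equilibrium solve produced non-finite displacements")
        return u.reshape(-1, 2)

    def _state_from_displacement(self, u: np.ndarray) -> MechanicalState:
        tri = self.mesh.triangles
        ue = np.empty((self.mesh.n_triangles, 6))
        ue[:, 0::2] = u[:, 0][tri]
        ue[:, 1::2] = u[:, 1][tri]
        s3 = np.einsum("ekl,el->ek", self._c @ self._b, ue)  # σxx, σyy, σxy
        szz = self.material.poissons_ratio * (s3[:, 0] + s3[:, 1])
        stress = np.column_stack([s3, szz])
        vm = von_mises(s3[:, 0], s3[:, 1], s3[:, 2], szz)
        return MechanicalState(u, stress, vm)

    def solve_cellularity_forcing(self, n_forcing: np.ndarray, lam: float) -> MechanicalState:
        """Equilibrium under the traction body force b = −λ∇N.

        ∇N is constant per element for P1 fields; the element load spreads
        −λ A_e ∇N equally over its three nodes.
        """
        nvals = np.asarray(n_forcing, float)
        if not np.all(np.isfinite(nvals)):
            raise SolverError("cellularity forcing contains non-finite values")
        if lam == 0.0:
            u = np.zeros((self.mesh.n_nodes, 2))
            return self._state_from_displacement(u)
        mesh = self.mesh
        grad_n = np.einsum("eid,ei->ed", mesh.shape_gradients, nvals[mesh.triangles])
        fe = -lam * (mesh.areas / 3.0)[:, None] * grad_n  # per-node share, per element
        load = np.zeros(2 * mesh.n_nodes)
        np.add.at(load, 2 * mesh.triangles.ravel(), np.repeat(fe[:, 0], 3))
        np.add.at(load, 2 * mesh.triangles.ravel() + 1, np.repeat(fe[:, 1], 3))
        return self._state_from_displacement(self._solve_load(load))

    def solve_body_force(self, f_nodal: np.ndarray) -> MechanicalState:
        """Equilibrium under an arbitrary nodal body force (µN/µm³ sense).

        The load vector uses the consistent P1 mass matrix applied to the
        nodal force samples, which keeps the manufactured-solution
        convergence order at two.
        """
        f = np.asarray(f_nodal, float)
        mesh = self.mesh
        tri = mesh.triangles
        fe = f[tri]  # (m, 3, 2)
        # consistent mass A/12 * [[2,1,1],[1,2,1],[1,1,2]]
        w = (mesh.areas / 12.0)[:, None, None]
        le = w * (fe + fe.sum(axis=1, keepdims=True))
        load = np.zeros(2 * mesh.n_nodes)
        np.add.at(load, 2 * tri.ravel(), le[..., 0].ravel())
        np.add.at(load, 2 * tri.ravel() + 1, le[..., 1].ravel())
        return self._state_from_displacement(self._solve_load(load))


def solve_equilibrium(
    n_forcing: np.ndarray, lam: float, material: MaterialMap, mesh: TriMesh
) -> MechanicalState:
    """One-shot equilibrium solve (builds and factorizes the system).

    Prefer holding an :class:`ElasticitySystem` when solving repeatedly.
    """
    return ElasticitySystem(mesh, material).solve_cellularity_forcing(n_forcing, lam)


# ----------------------------------------------------------------------------
# time stepping


def step_cellularity(
    n: np.ndarray,
    d_per_element: np.ndarray,
    k: float,
    theta: float,
    dt: float,
    mesh: TriMesh,
    lumped_mass: np.ndarray | None = None,
    stiffness: sparse.csr_matrix | None = None,
    overshoot_epsilon: float = 1e-6,
) -> np.ndarray:
    """One forward-Euler update of the lumped-mass Galerkin semi-discretization.

    Raises :class:`StabilityError` if ``dt`` exceeds the diffusion limit, and
    if the update overshoots [0, θ] by more than ``overshoot_epsilon``
    (small overshoot is clipped; large overshoot signals instability and is
    never silently hidden).
    """
    d = np.broadcast_to(np.asarray(d_per_element, float), (mesh.n_triangles,))
    limit = cfl_limit(float(d.max()), mesh, 1.0)
    if dt > limit:
        raise StabilityError(f"dt={dt} h exceeds the stability limit {limit:.6g} h")
    if lumped_mass is None:
        lumped_mass = mesh.lumped_mass()
    if stiffness is None:
        stiffness = assemble_diffusion_stiffness(mesh, d)
    n = np.asarray(n, float)
    n_new = n + dt * (-(stiffness @ n) / lumped_mass + k * n * (1.0 - n / theta))
    lo, hi = n_new.min(), n_new.max()
    if lo < -overshoot_epsilon or hi > theta + overshoot_epsilon:
        raise StabilityError(
            f"cellularity overshoot beyond epsilon: range [{lo:.3e}, {hi:.3e}]"
        )
    return np.clip(n_new, 0.0, theta)


@dataclass
class IntervalResult:
    """Output of one simulated imaging interval."""

    n_end: CellularityField
    displacement: np.ndarray  # (n_nodes, 2) incremental over the interval, µm
    diagnostics: pd.DataFrame  # per-step: time_h, total_mass, max_vm_stress_Pa, min_D_um2_per_h
    final_state: MechanicalState = field(repr=False, default=None)


def simulate_interval(
    n_start: CellularityField,
    params: BiophysicalParams,
    material: MaterialMap,
    mesh: TriMesh,
    config: SolverConfig | None = None,
    elasticity: ElasticitySystem | None = None,
) -> IntervalResult:
    """Advance the coupled system over one imaging interval.

    Alternates the quasi-static equilibrium solve (forced by N − N_start,
    re-solved every ``mechanics_update_every`` Euler steps) with explicit
    cellularity updates.  Returns the end-of-interval cellularity, the
    model-predicted incremental displacement field, and per-step diagnostics.
    """
    if config is None:
        config = SolverConfig(interval_hours=params.interval[1] - params.interval[0])
    if abs((params.interval[1] - params.interval[0]) - config.interval_hours) > 1e-9:
        raise ValueError("params.interval length does not match config.interval_hours")
    if elasticity is None:
        elasticity = ElasticitySystem(mesh, material)
    limit = cfl_limit(params.D0, mesh, config.cfl_safety)
    if config.dt > limit:
        raise StabilityError(
            f"dt={config.dt} h exceeds the safe stability limit {limit:.6g} h for D0={params.D0}"
        )

    lumped = mesh.lumped_mass()
    n = n_start.values.copy()
    n0 = n_start.values
    state = elasticity.solve_cellularity_forcing(np.zeros_like(n), params.lam)
    d_elem = np.full(mesh.n_triangles, params.D0)
    records = []
    t = params.interval[0]
    for step in range(config.n_steps):
        if step % config.mechanics_update_every == 0:
            state = elasticity.solve_cellularity_forcing(n - n0, params.lam)
            d_elem = effective_diffusion(params.D0, params.gamma, state.von_mises_stress)
        stiffness = assemble_diffusion_stiffness(mesh, d_elem)
        n = step_cellularity(
            n, d_elem, params.k, config.theta, config.dt, mesh,
            lumped_mass=lumped, stiffness=stiffness,
            overshoot_epsilon=config.overshoot_epsilon,
        )
        t += config.dt
        records.append(
            {
                "time_h": t,
                "total_mass": float(lumped @ n),
                "max_vm_stress_Pa": float(state.von_mises_stress.max()),
                "min_D_um2_per_h": float(d_elem.min()),
            }
        )
    # final incremental displacement for the full interval change
    state = elasticity.solve_cellularity_forcing(n - n0, params.lam)
    return IntervalResult(
        n_end=CellularityField(n, params.interval[1], theta=config.theta),
        displacement=state.displacement,
        diagnostics=pd.DataFrame.from_records(records),
        final_state=state,
    )
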