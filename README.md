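# spherofit

Biophysical characterization of multicellular tumor spheroid (MCTS)
invasion assays from standard two-channel time-lapse microscopy.

Conventional readouts of 3D spheroid drug-response assays — core and
invasive diameters — describe *that* a spheroid grew or shrank, but not
*why*. `spherofit` extracts mechanistic parameters instead: it fits a
mechanically-coupled reaction-diffusion model to pairs of consecutive
microscopy frames, yielding per-interval estimates of the cellular
diffusion coefficient **D₀** (µm²/h), the proliferation rate **k** (1/h),
and the cell-matrix traction coefficient **λ**. It is intended for
quantitative-biology and image-analysis groups running spheroid-in-gel
invasion assays (e.g. breast cancer lines embedded in collagen with
fluorescent fiducial beads), and for methodologists studying PDE-based
inverse problems on microscopy data.

## Model

Normalized cell density N(x, t) ∈ [0, θ], θ = 1, evolves on the imaged 2D
field as

```
∂N/∂t = ∇·(D ∇N) + k N (1 − N/θ)          logistic growth + motility
D     = D₀ exp(−γ σ_VM)                    stress-attenuated diffusion
∇·G∇u + ∇[G/(1−2ν)](∇·u) = λ∇N             elastic equilibrium of the gel
```

with σ_VM the von Mises stress of the displacement solution u, G the shear
modulus (2 kPa gel, ten-fold stiffer spheroid core, ν = 0.45, plane
strain), and γ a fixed coupling constant (default 2.5e−3 /Pa). The system
is discretized with P1 triangular finite elements (45 µm mean edges) and
explicit Euler steps (Δt = 0.125 h over 12 h intervals).

Estimation is sequential Levenberg-Marquardt between each pair of frames:
(D₀, k) against the observed cellularity map, then λ against the
bead-derived deformation field, alternated to convergence. The full
processing chain from raw images — tile stitching, ICP rigid registration
on bead centroids, plate-wide intensity normalization, ROI segmentation,
and multilevel-B-spline deformation fields from tracked beads — is
included, as is a synthetic phantom generator so everything is testable
with no external data.

## Worked example

Simulate one 12 h interval of an untreated-like spheroid and re-estimate
the generating parameters from its own noiseless output:

```python
from spherofit import (PhantomConfig, SolverConfig, FitConfig, make_phantom,
                       simulate_interval, BiophysicalParams)
from spherofit.inverse import fit_interval, ObservationPair

phantom = make_phantom(PhantomConfig(rng_seed=1))
truth = BiophysicalParams(D0=399.46, k=1.18e-2, lam=-1596.31, interval=(24.0, 36.0))
sim = simulate_interval(phantom.n_initial, truth, phantom.material,
                        phantom.mesh, SolverConfig())
obs = ObservationPair(phantom.n_initial, sim.n_end, sim.displacement)
fit = fit_interval(obs, phantom.mesh, phantom.material, SolverConfig(),
                   FitConfig(init_d0=800.0, init_k=0.024))
p = fit.params
print(f"D0 = {p.D0:8.2f} um^2/h   (generating 399.46)")
print(f"k  = {p.k:10.5f} /h     (generating 0.01180)")
print(f"lambda = {p.lam:9.2f}      (generating -1596.31)")
print(f"converged at outer iteration {fit.outer_iterations}; "
      f"last LM stop: {fit.convergence_reason}")
```

prints

```
D0 =   399.00 um^2/h   (generating 399.46)
k  =    0.01179 /h     (generating 0.01180)
lambda =  -1596.91      (generating -1596.31)
converged at outer iteration 2; last LM stop: absolute_objective
```

i.e. all three parameters are recovered to ~0.1% from initial guesses a
factor of two off, with the growth/traction alternation settling at its
second pass. The same interval produces a peak gel displacement of 1.28 µm
and peak von Mises stress of 109 Pa — the sub-pixel bead motions and
tens-of-pascals stresses typical of these assays.

## Command line

A full two-group synthetic study (3 systems per group, 6 intervals,
hours 24-96), through imaging, processing, fitting and reporting:

```
spherofit run --seed 1 --outdir study
```

writes per-system rendered frames, deformation fields, fitted parameter
trajectories (`fitted_parameters.csv`), diameters (`morphometrics.csv`),
a per-time-point group comparison table with t-test stars
(`group_table.csv`) and a `manifest.json` with checksums for
reproducibility. `spherofit --help` lists the stage-wise subcommands
(`simulate`, `process`, `fit`, `morpho`, `report`); a YAML file passed via
`--config` overrides any default (see `spherofit/config.py` for the
schema).

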