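# Methods

## The model

`spherofit` characterizes multicellular tumor spheroid (MCTS) invasion
assays by fitting a mechanically-coupled reaction-diffusion model to
time-lapse microscopy observations. The state variable is a normalized cell
density N(x, t) ∈ [0, θ] (θ = 1 after plate-wide intensity normalization),
governed on a fixed 2D domain by

    ∂N/∂t = ∇·(D ∇N) + k N (1 − N/θ)
    D     = D₀ exp(−γ σ_VM)
    ∇·G∇u + ∇[G/(1−2ν)](∇·u) − λ∇N = 0

The first equation is logistic growth plus random motility. The second
attenuates the global diffusion coefficient D₀ (µm²/h) wherever the
surrounding gel carries distortional (von Mises) stress σ_VM, through the
coupling constant γ (1/Pa). The third is quasi-static, isotropic linear
elasticity for the hydrogel displacement u (µm), forced by the cellularity
gradient through the traction coefficient λ (Pa per unit normalized
cellularity); G = E/2(1+ν) is the shear modulus. Fitted λ values in this
system are negative: the body force −λ∇N then points outward along the
falling density edge, displacing the gel away from the spheroid.

Assumptions inherited with the model: fluorescence intensity is linear in
cell number; parameters are spatially homogeneous and piecewise constant per
12 h imaging interval; mechanics are linear-elastic with uniform gel modulus
(2 kPa) and a ten-fold stiffer static spheroid core; the analysis is 2D
(maximum-intensity projections), plane strain, with ν = 0.45 for the
near-incompressible hydrogel. Convective flux from mitosis is neglected.

## Discretization

Space: Galerkin P1 (three-node triangular) finite elements on a structured
right-triangle mesh whose spacing is chosen so the mean edge length equals
the 45 µm target; for a 500 × 500 µm field this gives 196 nodes / 338
elements. One mesh serves the entire time course. Mechanics impose u = 0 on
the image border (the gel is anchored far from the spheroid); the cell
equation uses natural no-flux boundaries, which conserve total lumped-mass
cellularity exactly when k = λ = 0 (verified to 1e−8 over 12 h).

Time: fully explicit forward Euler with a row-sum lumped mass matrix,
Δt = 0.125 h over 12 h intervals. A stability guard enforces
Δt ≤ safety · h²_min/(4 D_max) (safety 0.9 by default) and refuses to run
otherwise; updates that overshoot [0, θ] by more than 1e−6 raise instead of
being clipped silently, because large overshoot signals instability. The
equilibrium problem is re-solved every Euler step by default (configurable
cadence) with the elastic forcing taken as N − N_start of the interval;
linearity makes the interval displacement independent of the static
baseline. The stiffness matrix is LU-factorized once per mesh/material, so
each re-solve is a back-substitution.

Verification: the elasticity solver shows the expected ≈O(h²) L2 convergence
against a manufactured solution (measured slope 1.83-1.92 over three
refinements); pure logistic growth matches the closed form to better than
1e−3 at the default step; halving Δt changes the end-of-interval state by
≈9e−4 (relative L2) for mesh-resolved initial profiles.

## Inverse estimation

Between each pair of consecutive frames, three parameters (D₀, k, λ) are
estimated sequentially: a Levenberg-Marquardt (LM) pass over (D₀, k)
minimizing the nodal sum-squared cellularity misfit with λ held fixed
(first pass: the arbitrary λ = 0, i.e. an uncoupled reaction-diffusion fit),
then an LM pass over λ minimizing the stacked X/Y displacement misfit with
(D₀, k) fixed, repeated until the triplet's maximum relative change between
passes falls below 1e−2 (cap: 10 passes). We count `outer_iterations` as the
passes that updated the triplet — the iteration at which the final values
were attained — and record the terminal confirming pass separately
(`outer_passes`); on noiseless synthetic intervals the parameters converge
at the second pass.

The LM core is a compact damped-normal-equations implementation with
Marquardt (curvature-relative) damping, forward-difference Jacobians
(relative step 1e−4 with per-parameter characteristic scales: 100 µm²/h,
1e−2 /h, 100 Pa), bound handling by trial-point clipping, and four stopping
rules checked on accepted steps: absolute objective < 1e−4 (applied to the
total sum-squared error), relative objective change < 1e−2, 500 iterations,
1000 function evaluations. Accepted steps never increase the objective (a
tested invariant), and the implementation is cross-checked against scipy's
trust-region least squares on standard curve-fitting problems. Bounds
default to D₀ ∈ [0, 1e4] µm²/h and k ∈ [−1, 1] /h (net death allowed); λ is
unbounded. Unstable trial points (CFL violations at extreme D₀) count as
rejected steps rather than aborting the fit.

Per-interval fits over a time course are independent, each initialized from
the previous interval's estimate. γ is not fitted: the model's cellularity
and displacement observables constrain it only weakly relative to D₀ and λ,
and it is exposed as a configurable constant with default 2.5e−3 /Pa — a
value that, at the stress levels these traction coefficients generate
(~100 Pa), attenuates local diffusivity by a physiologically plausible
~20-25%.

### The displacement objective and the measurement operator

The observed deformation exists physically only at the fiducial beads, and
the beads are excluded from the spheroid core — exactly where the model's
displacement field peaks. Comparing the model field directly against a
smooth reconstruction of the bead data therefore biases λ low (the
reconstruction cannot contain energy where there are no beads). The
displacement residual consequently passes the model field through the same
linear measurement operator as the data: sample at the matched bead
positions (P1 interpolation), reconstruct with the same multilevel B-spline
approximation, evaluate at the nodes. Reconstruction smoothing then affects
both sides identically and cancels from the objective. With this operator,
end-to-end recovery of all three parameters through rendering, registration
and field reconstruction is 0.2-1%; without it, λ is underestimated by
~15-25% at sub-pixel displacement scales. When observations are direct nodal
fields (simulation bypass), no operator is attached and the residual is the
plain nodal difference.

## Image processing

Per frame: maximum-intensity projection of each z-stack; mosaic stitching
that refines nominal stage positions by maximizing normalized
cross-correlation over tile overlaps (±5 px search; featureless overlaps
fall back to nominal positions with a warning); rigid registration of every
frame to the first via iterative closest point (ICP) on detected bead
centroids. Bead detection is Otsu thresholding → connected components
(minimum 2 px) → centroids weighted by intensity above threshold (which
removes the asymmetric-truncation bias; ≤0.03 px error on isolated spots),
with detections closer than one bead diameter (2 µm) merged. ICP uses
mutual-nearest-neighbor correspondences with distance trimming (drops the
worst 15% and anything past 3× the median) and closed-form (SVD) rigid
fits; because plain ICP only converges locally, it is seeded by a 0.5°-step
scan over centroid-aligned rotations scored by trimmed nearest-neighbor
distance. Recovery of synthetic transforms is exact to machine precision,
and within numerical noise under 10% outlier contamination.

Cellularity intensities are normalized plate-wide by the 99.99th-percentile
pooled pixel intensity (values above clip to 1), which defines the carrying
capacity θ = 1. ROIs come from Otsu thresholding followed by morphological
closing and largest-component selection.

Deformation fields between consecutive (rigidly aligned) bead frames are
obtained by the default *bead-tracking* route: centroids are matched by
mutual nearest neighbors (local-median consistency filtering rejects
clusters that merged differently in the two frames) and the scattered
per-bead displacements are approximated by a multilevel cubic B-spline
surface (coarse-to-fine lattice hierarchy, 4 levels from a 4-cell grid,
local least-squares lattice updates). An intensity-based alternative —
multi-resolution B-spline (FFD) registration minimizing the sum-squared
difference, via SimpleITK with a phase-correlation translation stage — is
provided (`deformation_method="intensity"`); it meets sub-pixel accuracy on
8 µm warps (mean endpoint error ≈0.36 µm) but its amplitude transfer
degrades for the ~0.2 px/interval motions typical of these assays, which is
why bead tracking is the default.

## Synthetic phantoms

The generator emulates the acquisition geometry of the assay: 500 × 500 µm
field at 5 µm pixels, seven frames 12 h apart from hour 24 to 96, a
radially symmetric initial spheroid (plateau of density 1 inside a 100 µm
core, Gaussian falloff of width 20 µm) and 300 beads placed uniformly in
the gel outside the core. Images render through a 1 px Gaussian PSF
(the smallest blur that avoids aliasing 2 µm beads at 5 µm pixels), with
optional additive Gaussian and Poisson-like noise (both off by default —
the reference microscope's noise is uncharacterized, so defaults are
noiseless and the noise model is illustrative). Bead trajectories advect
with the simulated incremental deformation sampled at the bead positions,
so ground truth and rendered motion agree by construction. Built-in
treated/untreated parameter presets use published per-interval group means
(and SDs for per-system variability), so a default two-group run reproduces
the characteristic invasive-versus-arrested contrast.

What the phantoms do not emulate: photorealistic nuclear texture, true 3D
stack structure (single-plane z-stacks by default), fluorescence bleaching,
ECM stiffness heterogeneity, or microscope-specific noise. Passing the
recovery tests therefore demonstrates the correctness and identifiability
of the estimation machinery under the model's own data-generating process —
not robustness to real-microscopy artifacts beyond those modeled.

## Morphometric comparators and statistics

Core diameter: equivalent-circle diameter 2√(area/π) of the supra-threshold
(default 0.5) region of the normalized image — chosen as an area-robust
definition since none is standard. Invasive diameter: maximum Feret
(longest caliper) diameter of the segmented ROI, computed from convex-hull
boundary pixels plus one pixel width. Group comparisons per time point use
the unpaired two-sample t-test — pooled-variance Student by default, the
textbook choice at n = 3 per group, with Welch behind a flag — at
α = 0.05, starred *, **, *** at p < 0.05, 0.01, 0.001.

A caveat established while validating against published group summaries:
recomputing the diffusion-column significance tiers from printed
means ± SDs (n = 3) yields p < 0.05 at all six time points, but the exact
star tier printed alongside those summaries is not always the tier the
closed-form t-test produces from them; the corresponding acceptance check
is left failing rather than weakened, since the computation is
deterministic and the inputs are fixed.

## Problem sizes and numerical defaults

The standard configuration — 100 × 100 px field, 196-node mesh, Δt =
0.125 h, 96 Euler steps and 96 equilibrium back-substitutions per interval —
simulates an interval in ≈0.3 s and completes a sequential three-parameter
fit in ≈4-6 s on one CPU core; a full two-group, three-systems-per-group,
six-interval study runs in a few minutes. These sizes match the acquisition
geometry the model targets, and all shipped tests and the acceptance script
use them.

## Known limitations

- γ is a fixed input, not estimated; mis-specifying it propagates into D₀.
- The stiffened core is static; real invasion remodels stiffness over time.
- Identifiability degrades for spatially uniform cellularity (D₀ drops out
  of the objective; the diagnostics expose the vanishing gradient).
- The initial frame's sharp plateau edge sits at the imaging model's
  resolution limit: its recovered cellularity carries ~5% L2 error from PSF
  blurring (later, smoother frames close below 1%).
- Interval displacement fitting assumes the incremental field; cumulative
  deformation is provided for display but is the composition of interval
  estimates, with no independent validation of the composition order.
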