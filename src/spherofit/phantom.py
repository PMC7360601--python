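"""Synthetic spheroid acquisitions with known ground truth.

Every other module in the package can be exercised without external data by
generating an in-silico spheroid: a radially symmetric initial cellularity
field (dense core plus smooth falloff into the gel), fiducial beads scattered
in the surrounding matrix, and a time-lapse image series produced by running
the coupled forward model and rendering the resulting fields through a simple
imaging model (Gaussian PSF, optional additive/shot noise).

The generator emulates the acquisition geometry of a typical spheroid
invasion assay: a 500 × 500 µm field at 5 µm pixels, seven frames 12 h apart
from hour 24 to hour 96, a core of radius ~100 µm, and ~300 two-micron beads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .forward import (
    BiophysicalParams,
    CellularityField,
    MaterialMap,
    SolverConfig,
    material_from_core,
    simulate_interval,
)
from .mesh import PixelGrid, TriMesh, build_mesh, grid_to_mesh, mesh_to_grid

#: Reference per-interval group-mean parameter trajectories (D0 µm²/h, k 1/h,
#: λ Pa per unit cellularity) for untreated and nab-paclitaxel-treated
#: MDA-MB-231 spheroids, keyed by interval end hour.  Used as generator
#: presets so treated/untreated phantom series reproduce the characteristic
#: invasive vs. growth-arrested behavior of the two groups.
GROUP_MEAN_TRAJECTORIES: dict[str, dict[int, tuple[float, float, float]]] = {
    "untreated": {
        36: (399.46, 1.18e-2, -1596.31),
        48: (352.70, 1.12e-2, -560.88),
        60: (256.72, 1.01e-2, -408.97),
        72: (248.27, 9.5e-3, -222.96),
        84: (243.17, 1.02e-3, -166.50),
        96: (219.83, 8.45e-3, -115.15),
    },
    "treated": {
        36: (95.79, 3.37e-3, -892.13),
        48: (68.04, 6.69e-3, -232.76),
        60: (57.33, 4.96e-3, -181.65),
        72: (56.67, 4.18e-3, -195.46),
        84: (52.84, 3.20e-3, -170.20),
        96: (19.87, 3.20e-4, -121.20),
    },
}

#: Matching per-interval group standard deviations, same ordering (D0, k, λ).
GROUP_SD_TRAJECTORIES: dict[str, dict[int, tuple[float, float, float]]] = {
    "untreated": {
        36: (31.99, 1.73e-3, 163.03),
        48: (43.77, 3.52e-3, 6.28),
        60: (41.08, 1.28e-3, 36.36),
        72: (37.28, 1.14e-3, 40.28),
        84: (36.16, 5.95e-4, 21.83),
        96: (36.91, 8.64e-4, 11.28),
    },
    "treated": {
        36: (29.36, 3.07e-3, 133.93),
        48: (44.57, 2.21e-3, 42.75),
        60: (48.54, 2.12e-3, 48.96),
        72: (45.43, 1.47e-3, 35.75),
        84: (47.09, 1.50e-3, 14.36),
        96: (7.15, 4.53e-4, 15.06),
    },
}


def group_params(group: str, gamma: float = 2.5e-3) -> list[BiophysicalParams]:
    """Six-interval parameter list (hours 24→96) from the group-mean presets."""
    traj = GROUP_MEAN_TRAJECTORIES[group]
    out = []
    for end_h in sorted(traj):
        d0, k, lam = traj[end_h]
        out.append(
            BiophysicalParams(D0=d0, k=k, lam=lam, gamma=gamma, interval=(end_h - 12, end_h))
        )
    return out


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and noise of the synthetic acquisition."""

    field_size_um: tuple[float, float] = (500.0, 500.0)
    pixel_size_um: float = 5.0
    core_radius_um: float = 100.0
    plateau_density: float = 1.0
    falloff_width_um: float = 20.0
    bead_count: int = 300
    bead_sigma_px: float = 1.0  # rendering PSF for the bead channel
    cell_sigma_px: float = 1.0  # rendering PSF for the cellularity channel
    noise_sigma: float = 0.0  # additive Gaussian, on the normalized [0, 1] scale
    shot_noise: bool = False
    shot_scale: float = 1000.0  # effective photon count at intensity 1
    mesh_target_edge_um: float = 45.0
    t_start_h: float = 24.0
    interval_h: float = 12.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius_um >= min(self.field_size_um) / 2:
            raise ValueError("core radius must be below half the field size")
        if self.bead_count <= 0:
            raise ValueError("bead count must be positive")
        if self.plateau_density <= 0 or self.plateau_density > 1.0:
            raise ValueError("plateau density must be in (0, 1]")

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(
            round(self.field_size_um[0] / self.pixel_size_um),
            round(self.field_size_um[1] / self.pixel_size_um),
            self.pixel_size_um,
        )


def radial_profile(r, config: PhantomConfig) -> np.ndarray:
    """Initial density: plateau inside the core, Gaussian falloff outside.

    N(r) = peak for r ≤ r_core, peak·exp(−(r−r_core)²/(2 w²)) beyond.
    """
    r = np.asarray(r, dtype=float)
    tail = np.exp(-((r - config.core_radius_um) ** 2) / (2.0 * config.falloff_width_um**2))
    return config.plateau_density * np.where(r <= config.core_radius_um, 1.0, tail)


@dataclass
class GroundTruth:
    """Everything the generator knows: the quantities estimation must recover."""

    params: list[BiophysicalParams]
    cellularity: list[CellularityField]  # nodal, one per frame
    deformations: list[np.ndarray]  # nodal (n_nodes, 2) per interval, µm
    bead_trajectories: np.ndarray  # (n_frames, n_beads, 2), µm
    times_h: np.ndarray


@dataclass
class Phantom:
    config: PhantomConfig
    mesh: TriMesh
    grid: PixelGrid
    n_initial: CellularityField
    bead_positions: np.ndarray  # (n_beads, 2), µm
    material: MaterialMap


def make_phantom(config: PhantomConfig) -> Phantom:
    """Build the initial state: mesh, cellularity profile, bead cloud, material."""
    mesh = build_mesh(config.field_size_um, config.mesh_target_edge_um)
    grid = config.grid
    center = np.asarray(config.field_size_um) / 2.0
    r = np.hypot(*(mesh.node_coords - center).T)
    n0 = CellularityField(radial_profile(r, config), config.t_start_h)

    rng = np.random.default_rng(config.rng_seed)
    beads = np.empty((0, 2))
    while beads.shape[0] < config.bead_count:
        cand = rng.uniform([0, 0], config.field_size_um, size=(config.bead_count * 2, 2))
        keep = np.hypot(*(cand - center).T) > config.core_radius_um  # beads live in the gel
        beads = np.vstack([beads, cand[keep]])
    beads = beads[: config.bead_count]

    material = material_from_core(mesh, n0.values)
    return Phantom(config, mesh, grid, n0, beads, material)


def render_cellularity(n_nodal: np.ndarray, phantom: Phantom) -> np.ndarray:
    """Project the nodal field to pixels and blur with the rendering PSF."""
    img = mesh_to_grid(n_nodal, phantom.mesh, phantom.grid)
    if phantom.config.cell_sigma_px > 0:
        img = ndimage.gaussian_filter(img, phantom.config.cell_sigma_px)
    return img


def render_beads(positions: np.ndarray, grid: PixelGrid, sigma_px: float = 1.0) -> np.ndarray:
    """Render unit-amplitude Gaussian spots at the given µm positions."""
    rc = grid.to_pixel_indices(positions)
    rows = np.arange(grid.height)[:, None, None]
    cols = np.arange(grid.width)[None, :, None]
    d2 = (rows - rc[:, 0][None, None, :]) ** 2 + (cols - rc[:, 1][None, None, :]) ** 2
    img = np.exp(-d2 / (2.0 * sigma_px**2)).sum(axis=2)
    return np.clip(img, 0.0, 1.0)


def add_noise(images: np.ndarray, config: PhantomConfig, seed: int) -> np.ndarray:
    """Apply the configured noise model; identity when both paths are off."""
    imgs = np.asarray(images, dtype=float)
    if config.noise_sigma == 0.0 and not config.shot_noise:
        return imgs.copy()
    rng = np.random.default_rng(seed)
    out = imgs.copy()
    if config.shot_noise:
        out = rng.poisson(np.clip(out, 0, None) * config.shot_scale) / config.shot_scale
    if config.noise_sigma > 0:
        out = out + rng.normal(0.0, config.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


@dataclass
class RenderedTimecourse:
    """Per-frame rendered images plus frame times (hours)."""

    cellularity_images: list[np.ndarray]
    bead_images: list[np.ndarray]
    times_h: np.ndarray
    grid: PixelGrid


def _displacement_at(points: np.ndarray, u_nodal: np.ndarray, mesh: TriMesh) -> np.ndarray:
    import matplotlib.tri as mtri

    tri = mesh.as_matplotlib()
    ux = mtri.LinearTriInterpolator(tri, u_nodal[:, 0])
    uy = mtri.LinearTriInterpolator(tri, u_nodal[:, 1])
    out = np.column_stack(
        [np.ma.filled(ux(points[:, 0], points[:, 1]), 0.0),
         np.ma.filled(uy(points[:, 0], points[:, 1]), 0.0)]
    )
    return out


def generate_timecourse(
    phantom: Phantom,
    params_per_interval: list[BiophysicalParams] | None = None,
    solver_config: SolverConfig | None = None,
) -> tuple[RenderedTimecourse, GroundTruth]:
    """Run the forward model over all intervals and render the image series.

    Beads advect with the incremental deformation of each interval sampled at
    their current positions, so by construction the trajectories equal the
    true deformation fields at the bead locations.
    """
    cfg = phantom.config
    if params_per_interval is None:
        params_per_interval = group_params("untreated")
    if solver_config is None:
        solver_config = SolverConfig(interval_hours=cfg.interval_h)
    n_frames = len(params_per_interval) + 1
    times = cfg.t_start_h + cfg.interval_h * np.arange(n_frames)

    fields = [phantom.n_initial]
    deformations: list[np.ndarray] = []
    bead_traj = np.empty((n_frames, phantom.bead_positions.shape[0], 2))
    bead_traj[0] = phantom.bead_positions
    for i, params in enumerate(params_per_interval):
        expected = (times[i], times[i + 1])
        if not np.allclose(params.interval, expected):
            params = replace(params, interval=expected)
        res = simulate_interval(
            fields[-1], params, phantom.material, phantom.mesh, solver_config
        )
        fields.append(res.n_end)
        deformations.append(res.displacement)
        bead_traj[i + 1] = bead_traj[i] + _displacement_at(
            bead_traj[i], res.displacement, phantom.mesh
        )

    cell_images, bead_images = [], []
    for i in range(n_frames):
        cell = render_cellularity(fields[i].values, phantom)
        bead = render_beads(bead_traj[i], phantom.grid, cfg.bead_sigma_px)
        cell_images.append(add_noise(cell, cfg, seed=cfg.rng_seed + 2 * i + 1))
        bead_images.append(add_noise(bead, cfg, seed=cfg.rng_seed + 2 * i + 2))

    truth = GroundTruth(params_per_interval, fields, deformations, bead_traj, times)
    rendered = RenderedTimecourse(cell_images, bead_images, times, phantom.grid)
    return rendered, truth


# ----------------------------------------------------------------------------
# raw-acquisition emission (tiled TIFFs + JSON sidecar)


def emit_raw_acquisition(
    rendered: RenderedTimecourse,
    outdir,
    tile_grid: tuple[int, int] = (3, 3),
    overlap_px: int = 12,
    jitter_px: int = 0,
    seed: int = 0,
) -> Path:
    """Write the rendered series as tiled single-plane z-stack TIFFs.

    The mosaic is cut into an overlapping tile grid with nominal stage
    positions recorded in a JSON sidecar; optional integer jitter perturbs
    the cut positions (but not the recorded nominal ones) to exercise
    stitching refinement.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    grid = rendered.grid
    nry, nrx = tile_grid
    h, w = grid.height, grid.width
    tile_h = (h + (nry - 1) * overlap_px) // nry
    tile_w = (w + (nrx - 1) * overlap_px) // nrx
    meta = {
        "pixel_size_um": grid.pixel_size,
        "mosaic_shape": [h, w],
        "tile_shape": [tile_h, tile_w],
        "times_h": [float(t) for t in rendered.times_h],
        "z_spacing_um": 0.0,
        "tiles": [],
    }
    for ti in range(nry):
        for tj in range(nrx):
            r0 = min(ti * (tile_h - overlap_px), h - tile_h)
            c0 = min(tj * (tile_w - overlap_px), w - tile_w)
            jr = jc = 0
            if jitter_px and (ti, tj) != (0, 0):
                jr = int(rng.integers(-jitter_px, jitter_px + 1))
                jc = int(rng.integers(-jitter_px, jitter_px + 1))
            cut_r = int(np.clip(r0 + jr, 0, h - tile_h))
            cut_c = int(np.clip(c0 + jc, 0, w - tile_w))
            meta["tiles"].append(
                {
                    "grid_index": [ti, tj],
                    "stage_row_px": r0,
                    "stage_col_px": c0,
                    "stage_x_um": c0 * grid.pixel_size,
                    "stage_y_um": (h - tile_h - r0) * grid.pixel_size,
                    "actual_cut_px": [cut_r, cut_c],
                }
            )
            for t, (cell, bead) in enumerate(
                zip(rendered.cellularity_images, rendered.bead_images)
            ):
                for chan, img in (("cell", cell), ("bead", bead)):
                    tile = img[cut_r : cut_r + tile_h, cut_c : cut_c + tile_w]
                    tifffile.imwrite(
                        outdir / f"t{t:02d}_r{ti}c{tj}_{chan}.tif",
                        tile[None].astype(np.float32),  # single-plane z-stack
                    )
    with open(outdir / "acquisition.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return outdir
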