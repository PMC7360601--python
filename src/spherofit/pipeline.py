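"""End-to-end orchestration: images → registered fields → observations.

Glue between the imaging chain and the model: processes a time-lapse series
(synthetic render or raw tiled acquisition) into registered normalized
cellularity maps, ROI masks and interval deformation fields, and interpolates
them onto the finite-element mesh as the observation pairs the inverse
estimation consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .forward import CellularityField
from .imaging import (
    BeadCloud,
    DeformationField,
    RigidTransform,
    ScatteredBSplineField,
    apply_rigid_to_image,
    detect_bead_centroids,
    ffd_register,
    icp_rigid_register,
    match_beads,
    max_intensity_projection,
    normalize_plate_intensity,
    segment_roi,
    stitch_tiles,
)
from .inverse import ObservationPair
from .mesh import PixelGrid, TriMesh, grid_to_mesh, interpolation_matrix
from .phantom import RenderedTimecourse


@dataclass
class ProcessedTimecourse:
    """Registered, normalized observation stack for one spheroid system."""

    times_h: np.ndarray
    cellularity_images: list[np.ndarray]  # normalized [0, 1], registered to frame 0
    bead_images: list[np.ndarray]  # registered to frame 0
    roi_masks: list[np.ndarray]
    deformation_fields: list[DeformationField]  # per interval, observed
    bead_clouds: list[BeadCloud]
    rigid_transforms: list[RigidTransform]  # frame -> frame 0
    grid: PixelGrid
    normalization_peak: float
    # per interval: matched bead reference positions and displacement vectors
    bead_matches: list[tuple[np.ndarray, np.ndarray]] | None = None


def load_raw_acquisition(acq_dir) -> RenderedTimecourse:
    """Read a tiled TIFF acquisition (with JSON sidecar) and stitch mosaics.

    Each tile is a multi-page z-stack; tiles are projected (MIP), then
    stitched per frame and channel with correlation-refined stage positions.
    """
    acq_dir = Path(acq_dir)
    with open(acq_dir / "acquisition.json") as fh:
        meta = json.load(fh)
    grid = PixelGrid(meta["mosaic_shape"][1], meta["mosaic_shape"][0], meta["pixel_size_um"])
    times = np.asarray(meta["times_h"], dtype=float)
    nominal = [(t["stage_row_px"], t["stage_col_px"]) for t in meta["tiles"]]
    cell_frames, bead_frames = [], []
    for t in range(len(times)):
        frames = {}
        for chan in ("cell", "bead"):
            tiles = []
            for tile_meta in meta["tiles"]:
                ti, tj = tile_meta["grid_index"]
                stack = tifffile.imread(acq_dir / f"t{t:02d}_r{ti}c{tj}_{chan}.tif")
                if stack.ndim == 2:
                    stack = stack[None]
                tiles.append(max_intensity_projection(stack))
            mosaic, _ = stitch_tiles(tiles, nominal, tuple(meta["mosaic_shape"]))
            frames[chan] = mosaic
        cell_frames.append(frames["cell"])
        bead_frames.append(frames["bead"])
    return RenderedTimecourse(cell_frames, bead_frames, times, grid)


def process_timecourse(
    rendered: RenderedTimecourse,
    register_rigid: bool = True,
    ffd_levels: int = 4,
    deformation_method: str = "beads",
) -> ProcessedTimecourse:
    """Run the full observation-processing chain on an image series.

    Frames are rigidly registered to the first frame through ICP on detected
    bead centroids, the cellularity channel is plate-normalized, ROIs are
    segmented, and consecutive registered bead frames are non-rigidly
    registered to yield the per-interval deformation fields.

    ``deformation_method`` selects how the dense field is obtained:
    ``"beads"`` (default) tracks matched bead centroids and fits a multilevel
    B-spline to the scattered displacements, which resolves the sub-pixel
    motions typical of these assays; ``"intensity"`` runs the image-based
    B-spline (FFD) registration instead.
    """
    grid = rendered.grid
    times = np.asarray(rendered.times_h, dtype=float)
    clouds = [
        detect_bead_centroids(img, grid, time_stamp=t)
        for img, t in zip(rendered.bead_images, times)
    ]
    transforms = [RigidTransform(0.0, np.zeros(2))]
    for cloud in clouds[1:]:
        if register_rigid and cloud.n_beads >= 3 and clouds[0].n_beads >= 3:
            transforms.append(icp_rigid_register(cloud, clouds[0]))
        else:
            transforms.append(RigidTransform(0.0, np.zeros(2)))

    cell_reg, bead_reg = [], []
    for cell, bead, tr in zip(rendered.cellularity_images, rendered.bead_images, transforms):
        if abs(tr.angle_rad) < 1e-12 and np.all(np.abs(tr.translation_um) < 1e-9):
            cell_reg.append(np.asarray(cell, dtype=float))
            bead_reg.append(np.asarray(bead, dtype=float))
        else:
            cell_reg.append(apply_rigid_to_image(cell, tr, grid))
            bead_reg.append(apply_rigid_to_image(bead, tr, grid))

    cell_norm, peak = normalize_plate_intensity(cell_reg)
    masks = [segment_roi(img) for img in cell_norm]
    fields: list[DeformationField] = []
    matches: list[tuple[np.ndarray, np.ndarray]] | None
    if deformation_method == "beads":
        matches = []
        domain = (grid.width * grid.pixel_size, grid.height * grid.pixel_size)
        reg_clouds = [detect_bead_centroids(img, grid) for img in bead_reg]
        for i in range(len(times) - 1):
            pts, disp = match_beads(reg_clouds[i], reg_clouds[i + 1])
            matches.append((pts, disp))
            surf = ScatteredBSplineField(pts, disp, domain, levels=ffd_levels)
            x, y = grid.pixel_centers_um()
            uv = surf(np.column_stack([x.ravel(), y.ravel()]))
            fields.append(
                DeformationField(
                    uv[:, 0].reshape(grid.height, grid.width),
                    uv[:, 1].reshape(grid.height, grid.width),
                    (times[i], times[i + 1]),
                )
            )
    elif deformation_method == "intensity":
        matches = None
        fields = [
            ffd_register(
                bead_reg[i], bead_reg[i + 1], grid,
                levels=ffd_levels, interval=(times[i], times[i + 1]),
            )
            for i in range(len(times) - 1)
        ]
    else:
        raise ValueError(f"unknown deformation_method {deformation_method!r}")
    return ProcessedTimecourse(
        times_h=times,
        cellularity_images=cell_norm,
        bead_images=bead_reg,
        roi_masks=masks,
        deformation_fields=fields,
        bead_clouds=clouds,
        rigid_transforms=transforms,
        grid=grid,
        normalization_peak=peak,
        bead_matches=matches,
    )


def deformation_at_nodes(field: DeformationField, grid: PixelGrid, mesh: TriMesh) -> np.ndarray:
    """Sample a pixel-grid deformation field at the mesh nodes (bilinear)."""
    rc = grid.to_pixel_indices(mesh.node_coords)
    ux = ndimage.map_coordinates(field.ux, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")
    uy = ndimage.map_coordinates(field.uy, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")
    return np.column_stack([ux, uy])


def bead_measurement_operator(
    mesh: TriMesh,
    grid: PixelGrid,
    bead_points: np.ndarray,
    levels: int = 4,
    coarsest_cells: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear operators of the bead observation process.

    Returns ``(B, M)``: ``B`` (n_nodes × n_beads) reconstructs a nodal field
    from per-bead samples via the multilevel B-spline surface, and
    ``M = B · P`` (n_nodes × n_nodes, with P the mesh-interpolation operator
    at the bead positions) applies the full sample-and-reconstruct
    measurement process to a nodal field.  Fitting the model through ``M``
    makes the comparison with bead-derived observations consistent: the
    reconstruction's smoothing affects both sides identically instead of
    biasing the traction estimate.
    """
    domain = (grid.width * grid.pixel_size, grid.height * grid.pixel_size)
    surf = ScatteredBSplineField(
        bead_points, np.eye(len(bead_points)), domain, levels, coarsest_cells
    )
    b = surf(mesh.node_coords)  # (n_nodes, n_beads)
    p = interpolation_matrix(mesh, bead_points)  # (n_beads, n_nodes)
    return b, b @ p.toarray()


def observations_from_processed(
    processed: ProcessedTimecourse, mesh: TriMesh
) -> list[ObservationPair]:
    """Interpolate the processed image stack onto the mesh as observation pairs.

    When per-bead matches are available the nodal deformation observation is
    the B-spline reconstruction evaluated at the nodes, and each pair carries
    the matching measurement operator for the displacement objective.
    """
    nodal = [
        CellularityField(
            np.clip(grid_to_mesh(img, processed.grid, mesh), 0.0, 1.0), t
        )
        for img, t in zip(processed.cellularity_images, processed.times_h)
    ]
    pairs = []
    for i in range(len(nodal) - 1):
        if processed.bead_matches is not None:
            pts, disp = processed.bead_matches[i]
            b, m = bead_measurement_operator(mesh, processed.grid, pts)
            u_obs = b @ disp
            pairs.append(
                ObservationPair(nodal[i], nodal[i + 1], u_obs, displacement_operator=m)
            )
        else:
            pairs.append(
                ObservationPair(
                    nodal[i], nodal[i + 1],
                    deformation_at_nodes(
                        processed.deformation_fields[i], processed.grid, mesh
                    ),
                )
            )
    return pairs


def observations_from_truth(fields, deformations) -> list[ObservationPair]:
    """Observation pairs taken directly from simulated nodal fields,
    bypassing rendering and registration (the pipeline's noiseless limit)."""
    return [
        ObservationPair(fields[i], fields[i + 1], deformations[i])
        for i in range(len(fields) - 1)
    ]
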