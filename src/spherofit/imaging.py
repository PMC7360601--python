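"""From raw time-lapse microscopy to registered cellularity and deformation maps.

The processing chain per acquisition:

1. maximum-intensity projection of each z-stack;
2. stitching of the tile grid, refining nominal stage positions by
   normalized cross-correlation over tile overlaps;
3. rigid registration of every frame to the first frame via an iterative
   closest point (ICP) alignment of detected fiducial-bead centroids;
4. plate-wide intensity normalization of the cellularity channel (top 0.01%
   of pooled pixels defines the carrying-capacity intensity);
5. automatic (Otsu) threshold segmentation of the spheroid ROI;
6. non-rigid multi-level B-spline (free-form deformation) registration of
   consecutive bead frames to obtain the observed deformation field.

All outputs carry physical units: bead centroids and displacement fields are
in µm with the package's y-up coordinate convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .mesh import PixelGrid


class PipelineError(RuntimeError):
    """Unrecoverable image-processing failure."""


# ----------------------------------------------------------------------------
# projection and stitching


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading z axis."""
    z = np.asarray(zstack)
    if z.ndim != 3 or z.shape[0] < 1:
        raise PipelineError(f"expected a non-empty z-stack, got shape {z.shape}")
    return z.max(axis=0)


def stitch_tiles(
    tiles: list[np.ndarray],
    nominal_positions_px: list[tuple[int, int]],
    mosaic_shape: tuple[int, int],
    search_radius_px: int = 5,
    min_correlation: float = 0.5,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Assemble a mosaic, refining each tile's position against what is
    already placed.

    Tiles are placed in the given order; each is shifted within
    ``search_radius_px`` of its nominal (row, col) position to maximize the
    normalized cross-correlation with the already-filled mosaic pixels.  A
    degenerate or weak correlation (featureless overlap) falls back to the
    nominal position with a warning.  Overlaps blend by maximum.

    Returns the mosaic and the refined positions.
    """
    h, w = mosaic_shape
    mosaic = np.zeros((h, w))
    filled = np.zeros((h, w), dtype=bool)
    refined: list[tuple[int, int]] = []
    for tile, (r0, c0) in zip(tiles, nominal_positions_px):
        th, tw = tile.shape
        best = (int(r0), int(c0))
        if filled.any():
            best_score = -np.inf
            found = False
            for dr in range(-search_radius_px, search_radius_px + 1):
                for dc in range(-search_radius_px, search_radius_px + 1):
                    r, c = r0 + dr, c0 + dc
                    if r < 0 or c < 0 or r + th > h or c + tw > w:
                        continue
                    m = filled[r : r + th, c : c + tw]
                    if m.sum() < 100:
                        continue
                    a = tile[m]
                    b = mosaic[r : r + th, c : c + tw][m]
                    sa, sb = a.std(), b.std()
                    if sa < 1e-12 or sb < 1e-12:
                        continue
                    score = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
                    if score > best_score:
                        best_score, best, found = score, (r, c), True
            if not found or best_score < min_correlation:
                warnings.warn(
                    "overlap correlation too weak; using nominal stage position",
                    stacklevel=2,
                )
                best = (int(r0), int(c0))
        r, c = best
        region = mosaic[r : r + th, c : c + tw]
        np.maximum(region, tile, out=region)
        filled[r : r + th, c : c + tw] = True
        refined.append(best)
    return mosaic, refined


# ----------------------------------------------------------------------------
# bead detection and rigid registration


@dataclass(frozen=True)
class BeadCloud:
    """Detected bead centroids in µm (y-up) at one time stamp."""

    coords_um: np.ndarray  # (n, 2)
    time_stamp: float = 0.0

    @property
    def n_beads(self) -> int:
        return self.coords_um.shape[0]


def detect_bead_centroids(
    image: np.ndarray,
    grid: PixelGrid,
    time_stamp: float = 0.0,
    min_area_px: int = 2,
    merge_distance_um: float = 2.0,
) -> BeadCloud:
    """Threshold → connected components → intensity-weighted centroids.

    Components below ``min_area_px`` are rejected; detections closer than one
    bead diameter are merged (averaged) so no two centroids violate the
    physical bead-spacing invariant.
    """
    img = np.asarray(image, dtype=float)
    if img.max() <= img.min():
        return BeadCloud(np.empty((0, 2)), time_stamp)
    thresh = threshold_otsu(img)
    binary = img > thresh
    labels = label(binary)
    # weighting by intensity above threshold removes the centroid bias from
    # the asymmetric truncation of a spot's thresholded footprint
    cents_px = [
        p.centroid_weighted
        for p in regionprops(labels, intensity_image=np.clip(img - thresh, 0, None))
        if p.area >= min_area_px
    ]
    if not cents_px:
        return BeadCloud(np.empty((0, 2)), time_stamp)
    rc = np.asarray(cents_px)
    xy = np.column_stack(
        [rc[:, 1] * grid.pixel_size, (grid.height - 1 - rc[:, 0]) * grid.pixel_size]
    )
    # merge near-coincident detections (union-find over close pairs)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(merge_distance_um, output_type="ndarray")
    parent = np.arange(len(xy))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        parent[find(a)] = find(b)
    roots = np.array([find(i) for i in range(len(xy))])
    merged = np.array([xy[roots == r].mean(axis=0) for r in np.unique(roots)])
    return BeadCloud(merged, time_stamp)


@dataclass(frozen=True)
class RigidTransform:
    """2D rotation-plus-translation, acting as p ↦ R(angle) p + t."""

    angle_rad: float
    translation_um: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "translation_um", np.asarray(self.translation_um, dtype=float)
        )

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation_um

    def inverse(self) -> "RigidTransform":
        r = self.rotation
        return RigidTransform(-self.angle_rad, -(r.T @ self.translation_um))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.angle_rad + other.angle_rad,
            self.rotation @ other.translation_um + self.translation_um,
        )


def _kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    angle = np.arctan2(r[1, 0], r[0, 0])
    t = qc - r @ pc
    return RigidTransform(angle, t)


def _icp_from(
    p: np.ndarray,
    q: np.ndarray,
    tree_q: cKDTree,
    init: RigidTransform,
    max_iterations: int,
    rel_tol: float,
) -> tuple[RigidTransform, float]:
    transform = init
    prev_err = np.inf
    err = np.inf
    for _ in range(max_iterations):
        moved = transform.apply(p)
        d_pq, idx_pq = tree_q.query(moved)
        _, idx_qp = cKDTree(moved).query(q)
        mutual = idx_qp[idx_pq] == np.arange(len(p))
        if mutual.sum() >= 6:
            # trimmed ICP: unmatched beads (replaced or newly appeared) end up
            # as the largest-distance pairs; drop the worst 15% plus anything
            # far beyond the median so they cannot bias the rigid fit
            d_mut = d_pq[mutual]
            cutoff = min(
                np.quantile(d_mut, 0.85), max(3.0 * np.median(d_mut), 1e-9)
            )
            mutual &= d_pq <= cutoff
        if mutual.sum() < 3:
            raise PipelineError("fewer than 3 reciprocal correspondences")
        err = float(np.mean(d_pq[mutual] ** 2))
        step = _kabsch(moved[mutual], q[idx_pq[mutual]])
        transform = step.compose(transform)
        if np.isfinite(prev_err) and prev_err - err <= rel_tol * max(prev_err, 1e-30):
            break
        prev_err = err
    return transform, err


def icp_rigid_register(
    cloud: BeadCloud,
    cloud_ref: BeadCloud,
    max_iterations: int = 100,
    rel_tol: float = 1e-8,
    scan_step_deg: float = 0.5,
) -> RigidTransform:
    """Rigid transform aligning ``cloud`` onto ``cloud_ref`` by ICP.

    Correspondences are nearest neighbors pruned to reciprocal (mutual)
    matches; each iteration solves the closed-form least-squares rigid fit
    and the loop stops when the mean squared correspondence distance changes
    by less than ``rel_tol`` relatively.

    Nearest-neighbor ICP only converges once the residual misalignment is
    below the typical bead spacing, so the iteration is seeded by a dense
    scan over centroid-aligned rotations, scored by a trimmed (80%)
    nearest-neighbor distance that tolerates a minority of unmatched beads.
    """
    p, q = cloud.coords_um, cloud_ref.coords_um
    if p.shape[0] < 3 or q.shape[0] < 3:
        raise PipelineError("ICP needs at least 3 points in each cloud")
    for pts in (p, q):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise PipelineError("degenerate (collinear) bead geometry")
    tree_q = cKDTree(q)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p_centered = p - pc
    n_keep = max(3, int(0.8 * len(p)))
    best_angle, best_score = 0.0, np.inf
    for angle in np.arange(0.0, 360.0, scan_step_deg):
        rot = RigidTransform(np.deg2rad(angle), np.zeros(2))
        d, _ = tree_q.query(p_centered @ rot.rotation.T + qc)
        score = np.sort(d)[:n_keep].mean()
        if score < best_score:
            best_angle, best_score = np.deg2rad(angle), score
    rot = RigidTransform(best_angle, np.zeros(2))
    init = RigidTransform(best_angle, qc - rot.rotation @ pc)
    transform, _ = _icp_from(p, q, tree_q, init, max_iterations, rel_tol)
    return transform


def apply_rigid_to_image(
    image: np.ndarray, transform: RigidTransform, grid: PixelGrid, order: int = 1
) -> np.ndarray:
    """Resample an image under a rigid transform given in µm, y-up.

    The output at pixel x takes the input value at T⁻¹(x), i.e. the image is
    moved forward by ``transform``.
    """
    inv = transform.inverse()
    # pixel (row, col) -> µm, apply inverse, back to (row, col)
    a_px2um = np.array([[0.0, grid.pixel_size], [-grid.pixel_size, 0.0]])
    b_px2um = np.array([0.0, (grid.height - 1) * grid.pixel_size])
    a_um2px = np.linalg.inv(a_px2um)
    m = a_um2px @ inv.rotation @ a_px2um
    off = a_um2px @ (inv.rotation @ b_px2um + inv.translation_um - b_px2um)
    return ndimage.affine_transform(
        np.asarray(image, float), m, offset=off, order=order, mode="nearest"
    )


# ----------------------------------------------------------------------------
# normalization and segmentation


def normalize_plate_intensity(images: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Scale all images by the 99.99th-percentile intensity of the pooled
    pixel population (the plate-wide carrying-capacity intensity); values
    above the peak clip to 1."""
    if not images:
        raise PipelineError("no images to normalize")
    pooled = np.concatenate([np.asarray(im, float).ravel() for im in images])
    peak = float(np.percentile(pooled, 99.99))
    if peak <= 0:
        raise PipelineError("no dynamic range: pooled 99.99th percentile is not positive")
    return [np.clip(np.asarray(im, float) / peak, 0.0, 1.0) for im in images], peak


def segment_roi(normalized_image: np.ndarray, closing_radius_px: int = 2) -> np.ndarray:
    """Otsu threshold → morphological closing → largest connected component.

    Components that merge with the largest one after closing are kept (they
    belong to the invading spheroid); isolated debris is dropped.  An image
    without foreground yields an empty mask with a warning.
    """
    img = np.asarray(normalized_image, dtype=float)
    if img.max() <= img.min():
        warnings.warn("image has no dynamic range; returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    binary = img > threshold_otsu(img)
    if not binary.any():
        warnings.warn("empty foreground after threshold", stacklevel=2)
        return binary
    closed = closing(binary, disk(closing_radius_px))
    labels = label(closed)
    largest = np.argmax(np.bincount(labels[labels > 0]))
    return (labels == largest) & closed


# ----------------------------------------------------------------------------
# scattered-data multilevel B-spline approximation (bead tracking route)


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """(4, n) uniform cubic B-spline basis values at local coordinates t∈[0,1]."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


def _cell_coords(x: np.ndarray, h: float, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.floor(x / h).astype(int)
    i = np.clip(i, 0, n_cells - 1)
    return i, x / h - i


class ScatteredBSplineField:
    """Multilevel cubic B-spline approximation of scattered 2D samples.

    The classic coarse-to-fine lattice hierarchy: each level fits the residual
    of the previous one with a control grid of half the spacing, using the
    local least-squares lattice update (no global solve).  Far from any data
    the surface decays to the coarse-level trend rather than oscillating.
    """

    def __init__(
        self,
        points: np.ndarray,
        values: np.ndarray,
        domain: tuple[float, float],
        levels: int = 4,
        coarsest_cells: int = 4,
    ):
        self.domain = domain
        self.lattices: list[tuple[np.ndarray, float, int, int]] = []
        pts = np.asarray(points, dtype=float)
        vals = np.asarray(values, dtype=float)
        self._scalar = vals.ndim == 1
        resid = vals.reshape(len(pts), -1).copy()
        nx = ny = coarsest_cells
        for _ in range(levels):
            hx, hy = domain[0] / nx, domain[1] / ny
            phi = self._ba_fit(pts, resid, hx, hy, nx, ny)
            self.lattices.append((phi, hx, nx, ny))
            resid = resid - self._eval_lattice(pts, phi, hx, hy, nx, ny)
            nx *= 2
            ny *= 2

    @staticmethod
    def _ba_fit(pts, z, hx, hy, nx, ny):
        ix, sx = _cell_coords(pts[:, 0], hx, nx)
        iy, sy = _cell_coords(pts[:, 1], hy, ny)
        wx = _bspline_weights(sx)  # (4, n)
        wy = _bspline_weights(sy)
        w = wx[:, None, :] * wy[None, :, :]  # (4, 4, n)
        s = (w**2).sum(axis=(0, 1))  # per-point weight norm
        m = z.shape[1]
        num = np.zeros((nx + 3, ny + 3, m))
        den = np.zeros((nx + 3, ny + 3))
        for k in range(4):
            for l in range(4):
                wkl = w[k, l]
                np.add.at(num, (ix + k, iy + l), (wkl**3 / s)[:, None] * z)
                np.add.at(den, (ix + k, iy + l), wkl**2)
        phi = np.zeros_like(num)
        nonzero = den > 0
        phi[nonzero] = num[nonzero] / den[nonzero, None]
        return phi

    @staticmethod
    def _eval_lattice(pts, phi, hx, hy, nx, ny):
        ix, sx = _cell_coords(pts[:, 0], hx, nx)
        iy, sy = _cell_coords(pts[:, 1], hy, ny)
        wx = _bspline_weights(sx)
        wy = _bspline_weights(sy)
        out = np.zeros((len(pts), phi.shape[2]))
        for k in range(4):
            for l in range(4):
                out += (wx[k] * wy[l])[:, None] * phi[ix + k, iy + l]
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        out = None
        for phi, hx, nx, ny in self.lattices:
            hy = self.domain[1] / ny
            term = self._eval_lattice(pts, phi, hx, hy, nx, ny)
            out = term if out is None else out + term
        return out[:, 0] if self._scalar else out


def match_beads(
    cloud_ref: BeadCloud,
    cloud_moving: BeadCloud,
    max_displacement_um: float = 15.0,
    outlier_mad_factor: float = 5.0,
    outlier_floor_um: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair beads between frames and return (ref positions, displacements).

    Mutual nearest neighbors within ``max_displacement_um`` are paired;
    pairs whose displacement deviates from the local (5-neighbor) median by
    more than ``outlier_mad_factor`` × MAD + floor are dropped — these are
    typically clusters that merged differently in the two frames.
    """
    p, q = cloud_ref.coords_um, cloud_moving.coords_um
    if len(p) < 4 or len(q) < 4:
        raise PipelineError("too few beads to build a deformation field")
    tree_q = cKDTree(q)
    d_pq, idx_pq = tree_q.query(p)
    _, idx_qp = cKDTree(p).query(q)
    mutual = (idx_qp[idx_pq] == np.arange(len(p))) & (d_pq < max_displacement_um)
    pr = p[mutual]
    disp = q[idx_pq[mutual]] - pr
    if len(pr) >= 6:
        k = min(6, len(pr))
        _, nn = cKDTree(pr).query(pr, k=k)
        local_med = np.median(disp[nn[:, 1:]], axis=1)
        resid = np.hypot(*(disp - local_med).T)
        mad = np.median(resid)
        keep = resid <= outlier_mad_factor * mad + outlier_floor_um
        pr, disp = pr[keep], disp[keep]
    return pr, disp


def bead_deformation_field(
    image_ref: np.ndarray,
    image_moving: np.ndarray,
    grid: PixelGrid,
    levels: int = 4,
    coarsest_cells: int = 4,
    interval: tuple[float, float] = (0.0, 0.0),
) -> DeformationField:
    """Observed deformation field from tracked bead centroids.

    Bead centroids are detected in both (rigidly pre-aligned) frames, paired,
    and the scattered per-bead displacement vectors are approximated by a
    multilevel B-spline surface per component, evaluated densely on the pixel
    grid.  For sparse sub-pixel bead motion this is substantially more
    accurate than intensity-based matching, because each bead centroid
    localizes to a small fraction of a pixel.
    """
    c_ref = detect_bead_centroids(image_ref, grid)
    c_mov = detect_bead_centroids(image_moving, grid)
    pts, disp = match_beads(c_ref, c_mov)
    domain = (grid.width * grid.pixel_size, grid.height * grid.pixel_size)
    fx = ScatteredBSplineField(pts, disp[:, 0], domain, levels, coarsest_cells)
    fy = ScatteredBSplineField(pts, disp[:, 1], domain, levels, coarsest_cells)
    x, y = grid.pixel_centers_um()
    pix = np.column_stack([x.ravel(), y.ravel()])
    ux = fx(pix).reshape(grid.height, grid.width)
    uy = fy(pix).reshape(grid.height, grid.width)
    return DeformationField(ux, uy, interval)


# ----------------------------------------------------------------------------
# non-rigid (free-form deformation) registration


@dataclass(frozen=True)
class DeformationField:
    """X/Y displacement per pixel in µm (y-up sense), for one interval."""

    ux: np.ndarray
    uy: np.ndarray
    interval: tuple[float, float] = (0.0, 0.0)
    provenance: str = "observed"  # observed | model

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)


def ffd_register(
    image_ref: np.ndarray,
    image_moving: np.ndarray,
    grid: PixelGrid,
    levels: int = 4,
    coarsest_mesh: int = 3,
    interval: tuple[float, float] = (0.0, 0.0),
    iterations_per_level: int = 60,
) -> DeformationField:
    """Multi-resolution cubic B-spline registration of two bead images.

    A coarse-to-fine hierarchy of control grids (``levels`` levels, grid
    density doubling per level from ``coarsest_mesh``) minimizes the
    sum-squared intensity difference; the converged transform is evaluated as
    a dense displacement field on the pixel grid, in µm with y-up sign.

    ``image_ref`` is frame t_i and ``image_moving`` frame t_{i+1}; the
    returned field maps material points of the reference frame to their
    displaced positions (u(x) such that moving(x + u) ≈ ref(x)).  A global
    sub-pixel translation (phase correlation) is estimated first and the
    B-spline hierarchy refines the residual, so bulk drift does not have to
    be expressed through control-point displacements.
    """
    from skimage.registration import phase_cross_correlation

    ref = np.asarray(image_ref, dtype=np.float64)
    mov = np.asarray(image_moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise PipelineError("images must share shape for non-rigid registration")
    if np.allclose(ref, mov):
        zero = np.zeros(ref.shape)
        return DeformationField(zero, zero.copy(), interval)

    fixed = sitk.GetImageFromArray(ref)
    moving = sitk.GetImageFromArray(mov)
    for im in (fixed, moving):
        im.SetSpacing((grid.pixel_size, grid.pixel_size))

    # global translation stage: object displacement is minus the registered
    # image shift; sitk physical axes follow the array (y image-down)
    shift_px, _, _ = phase_cross_correlation(ref, mov, upsample_factor=100)
    bulk = sitk.TranslationTransform(
        2, (-shift_px[1] * grid.pixel_size, -shift_px[0] * grid.pixel_size)
    )

    tx0 = sitk.BSplineTransformInitializer(fixed, [coarsest_mesh, coarsest_mesh], order=3)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGS2(numberOfIterations=iterations_per_level)
    reg.SetMovingInitialTransform(bulk)
    scale_factors = [2**lvl for lvl in range(levels)]
    shrink = [2 ** max(0, levels - 1 - lvl) for lvl in range(levels)]
    smooth = [max(0, levels - 2 - lvl) for lvl in range(levels)]
    reg.SetInitialTransformAsBSpline(tx0, inPlace=True, scaleFactors=scale_factors)
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(smooth)
    try:
        bspline = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # keep best-so-far behavior
        warnings.warn(f"non-rigid registration did not fully converge: {exc}", stacklevel=2)
        bspline = tx0

    transform = sitk.CompositeTransform(2)
    transform.AddTransform(bulk)  # applied last: T(x) = bulk(bspline(x))
    transform.AddTransform(bspline)
    field = sitk.TransformToDisplacementField(
        transform,
        sitk.sitkVectorFloat64,
        fixed.GetSize(),
        fixed.GetOrigin(),
        fixed.GetSpacing(),
        fixed.GetDirection(),
    )
    arr = sitk.GetArrayFromImage(field)  # (rows, cols, [dx, dy-image-down]) in µm
    return DeformationField(arr[..., 0], -arr[..., 1], interval)
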