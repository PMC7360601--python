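"""Triangular finite-element discretization of the microscopy field of view.

The imaged domain is a rectangle in physical micrometres.  A single mesh of
three-node (P1) triangles is built once per acquisition and reused for the
full time course; all fields (cellularity, displacement) live either on the
pixel grid of the microscope or on the mesh nodes, and this module moves
values between the two representations.

Coordinate convention
---------------------
The mesh lives in physical µm with the origin at the image's *lower-left
pixel center* and mathematical y-up.  Image arrays are indexed ``[row, col]``
with row 0 at the *top*, so every conversion between arrays and mesh
coordinates flips the row axis exactly once, here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib.tri as mtri
import numpy as np
from scipy import ndimage


class MeshError(ValueError):
    """Invalid mesh construction arguments or mesh/field mismatch."""


@dataclass(frozen=True)
class PixelGrid:
    """Geometry of a single-channel image: shape in pixels plus pixel pitch.

    ``width`` is the number of columns (x), ``height`` the number of rows (y).
    Pixel centers sit at integer multiples of ``pixel_size``; the physical
    extent of the sampled area is ``shape * pixel_size``.
    """

    width: int
    height: int
    pixel_size: float = 5.0

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise MeshError(f"grid must be at least 2x2, got {self.width}x{self.height}")
        if not self.pixel_size > 0:
            raise MeshError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical extent (x, y) in µm."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center as 2D arrays (image row order)."""
        cols = np.arange(self.width) * self.pixel_size
        rows = (self.height - 1 - np.arange(self.height)) * self.pixel_size
        x, y = np.meshgrid(cols, rows)
        return x, y

    def to_pixel_indices(self, xy_um: np.ndarray) -> np.ndarray:
        """Map physical (x, y) µm coordinates to fractional (row, col) indices."""
        xy = np.asarray(xy_um, dtype=float)
        col = xy[..., 0] / self.pixel_size
        row = (self.height - 1) - xy[..., 1] / self.pixel_size
        return np.stack([row, col], axis=-1)


@dataclass
class TriMesh:
    """P1 triangulation of a rectangular domain.

    Attributes
    ----------
    node_coords : (n_nodes, 2) float array, physical µm, y-up.
    triangles : (n_tri, 3) int array, counter-clockwise node triplets.
    boundary_mask : (n_nodes,) bool, True for nodes on the rectangle border.
    target_edge_length : requested mean edge length in µm.
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    boundary_mask: np.ndarray
    target_edge_length: float = 45.0
    # element geometry caches, filled lazily
    _areas: np.ndarray | None = field(default=None, repr=False)
    _grads: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def areas(self) -> np.ndarray:
        """Signed triangle areas; positive for the CCW orientation invariant."""
        if self._areas is None:
            self._compute_geometry()
        return self._areas

    @property
    def shape_gradients(self) -> np.ndarray:
        """(n_tri, 3, 2) constant gradients of the three P1 basis functions."""
        if self._grads is None:
            self._compute_geometry()
        return self._grads

    def _compute_geometry(self) -> None:
        p = self.node_coords[self.triangles]  # (m, 3, 2)
        x, y = p[..., 0], p[..., 1]
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
        self._areas = 0.5 * area2
        self._grads = np.stack([b, c], axis=2) / area2[:, None, None]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (n_edges, 2) sorted-index array."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.node_coords[e[:, 0]] - self.node_coords[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def min_edge_length(self) -> float:
        return float(self.edge_lengths().min())

    def lumped_mass(self) -> np.ndarray:
        """Row-sum lumped mass: one third of adjacent triangle areas per node."""
        m = np.zeros(self.n_nodes)
        np.add.at(m, self.triangles.ravel(), np.repeat(self.areas / 3.0, 3))
        return m

    def as_matplotlib(self) -> mtri.Triangulation:
        return mtri.Triangulation(
            self.node_coords[:, 0], self.node_coords[:, 1], self.triangles
        )


def build_mesh(domain_extent_um, target_edge_um: float = 45.0) -> TriMesh:
    """Build a structured right-triangle mesh of a rectangular domain.

    Each grid cell is split along its lower-left to upper-right diagonal into
    two CCW triangles.  The grid spacing is chosen so that the *mean* edge
    length (two axis-aligned edges and one diagonal per cell) equals
    ``target_edge_um``: for square cells of side s the mean is s(2 + √2)/3.

    Parameters
    ----------
    domain_extent_um : (width, height) of the domain in µm.
    target_edge_um : requested mean element edge length in µm.
    """
    wx, wy = (float(v) for v in np.ravel(domain_extent_um))
    if wx <= 0 or wy <= 0:
        raise MeshError(f"domain extent must be positive, got ({wx}, {wy})")
    if not target_edge_um > 0:
        raise MeshError(f"target edge length must be positive, got {target_edge_um}")
    if target_edge_um > min(wx, wy) / 2:
        raise MeshError(
            f"target edge {target_edge_um} µm too coarse for extent ({wx}, {wy}) µm"
        )
    spacing = target_edge_um * 3.0 / (2.0 + np.sqrt(2.0))
    nx = max(2, round(wx / spacing))
    ny = max(2, round(wy / spacing))
    xs = np.linspace(0.0, wx, nx + 1)
    ys = np.linspace(0.0, wy, ny + 1)
    xx, yy = np.meshgrid(xs, ys)  # row-major over y then x, y increasing
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(i, j):  # j along y, i along x
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            tris.append([a, b, c])  # CCW in y-up coordinates
            tris.append([a, c, d])
    triangles = np.asarray(tris, dtype=np.int64)

    on_border = (
        np.isclose(nodes[:, 0], 0.0)
        | np.isclose(nodes[:, 0], wx)
        | np.isclose(nodes[:, 1], 0.0)
        | np.isclose(nodes[:, 1], wy)
    )
    mesh = TriMesh(nodes, triangles, on_border, target_edge_length=float(target_edge_um))
    if np.any(mesh.areas <= 0):
        raise MeshError("mesh construction produced a non-positive triangle area")
    return mesh


def grid_to_mesh(values: np.ndarray, grid: PixelGrid, mesh: TriMesh) -> np.ndarray:
    """Bilinearly interpolate a pixel field at the mesh nodes.

    Node coordinates outside the span of pixel centers (e.g. the far domain
    edge at ``width * pixel_size``, half a pixel beyond the last center) are
    clamped to the nearest pixel.
    """
    img = np.asarray(values, dtype=float)
    if img.shape != (grid.height, grid.width):
        raise MeshError(f"image shape {img.shape} does not match grid {grid.height}x{grid.width}")
    if not np.all(np.isfinite(img)):
        raise MeshError("image contains non-finite values")
    rc = grid.to_pixel_indices(mesh.node_coords)
    return ndimage.map_coordinates(img, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")


def mesh_to_grid(
    nodal_values: np.ndarray, mesh: TriMesh, grid: PixelGrid, fill: float = 0.0
) -> np.ndarray:
    """Render a nodal field onto the pixel grid by barycentric interpolation.

    Pixels whose centers fall outside the mesh receive ``fill``.
    """
    v = np.asarray(nodal_values, dtype=float)
    if v.shape != (mesh.n_nodes,):
        raise MeshError(f"expected {mesh.n_nodes} nodal values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise MeshError("nodal values contain non-finite entries")
    interp = mtri.LinearTriInterpolator(mesh.as_matplotlib(), v)
    x, y = grid.pixel_centers_um()
    out = interp(x, y)
    return np.ma.filled(out, fill)


def interpolation_matrix(mesh: TriMesh, points_um: np.ndarray):
    """Sparse (n_points, n_nodes) P1 interpolation operator at arbitrary points.

    Row i holds the barycentric weights of point i in its containing
    triangle; points outside the mesh collapse onto their nearest node.
    """
    from scipy import sparse as _sparse

    pts = np.asarray(points_um, dtype=float)
    finder = mesh.as_matplotlib().get_trifinder()
    tri_idx = finder(pts[:, 0], pts[:, 1])
    rows, cols, vals = [], [], []
    for i, (pt, ti) in enumerate(zip(pts, tri_idx)):
        if ti < 0:
            d = np.linalg.norm(mesh.node_coords - pt, axis=1)
            rows.append(i)
            cols.append(int(np.argmin(d)))
            vals.append(1.0)
            continue
        nodes = mesh.triangles[ti]
        a, b, c = mesh.node_coords[nodes]
        t = np.column_stack([b - a, c - a])
        lb, lc = np.linalg.solve(t, pt - a)
        for n, w in zip(nodes, (1.0 - lb - lc, lb, lc)):
            rows.append(i)
            cols.append(int(n))
            vals.append(float(w))
    return _sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(pts), mesh.n_nodes)
    )


def save_mesh_txt(mesh: TriMesh, nodes_path, elements_path) -> None:
    """Write plain-text node and element lists (one record per line)."""
    with open(nodes_path, "w") as fh:
        for i, (x, y) in enumerate(mesh.node_coords):
            fh.write(f"{i} {x:.9g} {y:.9g}\n")
    with open(elements_path, "w") as fh:
        for i, (a, b, c) in enumerate(mesh.triangles):
            fh.write(f"{i} {a} {b} {c}\n")


def load_mesh_txt(nodes_path, elements_path, target_edge_um: float = 45.0) -> TriMesh:
    """Read a mesh written by :func:`save_mesh_txt`."""
    nd = np.loadtxt(nodes_path, ndmin=2)
    el = np.loadtxt(elements_path, dtype=np.int64, ndmin=2)
    nodes = nd[np.argsort(nd[:, 0]), 1:3]
    tris = el[np.argsort(el[:, 0]), 1:4]
    x, y = nodes[:, 0], nodes[:, 1]
    on_border = (
        np.isclose(x, x.min()) | np.isclose(x, x.max())
        | np.isclose(y, y.min()) | np.isclose(y, y.max())
    )
    return TriMesh(nodes, tris, on_border, target_edge_length=target_edge_um)
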