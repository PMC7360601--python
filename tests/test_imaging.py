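"""Image pipeline: projection, stitching, detection, registration, fields."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.spatial import cKDTree

from spherofit.imaging import (
    BeadCloud,
    PipelineError,
    RigidTransform,
    ScatteredBSplineField,
    bead_deformation_field,
    detect_bead_centroids,
    ffd_register,
    icp_rigid_register,
    match_beads,
    max_intensity_projection,
    normalize_plate_intensity,
    segment_roi,
    stitch_tiles,
)
from spherofit.mesh import PixelGrid
from spherofit.phantom import render_beads


@pytest.fixture(scope="module")
def bead_scene(grid100):
    """300 beads outside a central core, plus their rendered image."""
    rng = np.random.default_rng(0)
    pts = []
    while len(pts) < 300:
        c = rng.uniform(0, 500, size=2)
        if np.hypot(c[0] - 250, c[1] - 250) > 100:
            pts.append(c)
    pts = np.asarray(pts)
    return pts, render_beads(pts, grid100, 1.0)


class TestMaxIntensityProjection:
    def test_single_plane_is_identity(self):
        img = np.random.default_rng(1).random((1, 20, 20))
        assert np.array_equal(max_intensity_projection(img), img[0])

    def test_matches_per_pixel_loop_oracle(self):
        stack = np.random.default_rng(2).random((5, 12, 9))
        mip = max_intensity_projection(stack)
        for r in range(12):
            for c in range(9):
                assert mip[r, c] == max(stack[z, r, c] for z in range(5))

    def test_all_zero_stack(self):
        assert np.array_equal(max_intensity_projection(np.zeros((3, 4, 4))), np.zeros((4, 4)))

    def test_empty_stack_raises(self):
        with pytest.raises(PipelineError):
            max_intensity_projection(np.zeros((4, 4)))


def _cut_tiles(mosaic, tile, overlap, jitter=None):
    """Cut a 2x2 tile grid; optional per-tile jitter applied to the cut."""
    h, w = mosaic.shape
    th = (h + overlap) // 2
    tw = (w + overlap) // 2
    tiles, nominal = [], []
    k = 0
    for ti in range(2):
        for tj in range(2):
            r0 = min(ti * (th - overlap), h - th)
            c0 = min(tj * (tw - overlap), w - tw)
            if jitter is None or (ti, tj) == (0, 0):
                jr, jc = 0, 0
            else:
                jr, jc = jitter[k]
                k += 1
            tiles.append(mosaic[r0 + jr : r0 + jr + th, c0 + jc : c0 + jc + tw])
            nominal.append((r0, c0))
    return tiles, nominal


class TestStitching:
    def test_exact_reassembly_at_nominal_positions(self, bead_scene):
        _, mosaic = bead_scene
        tiles, nominal = _cut_tiles(mosaic, None, overlap=14)
        out, refined = stitch_tiles(tiles, nominal, mosaic.shape)
        assert refined == nominal
        assert np.allclose(out, mosaic)

    def test_recovers_injected_jitter_exactly(self, bead_scene):
        _, mosaic = bead_scene
        jitter = [(2, -3), (-1, 3), (3, 2)]
        tiles, nominal = _cut_tiles(mosaic, None, overlap=14, jitter=jitter)
        _, refined = stitch_tiles(tiles, nominal, mosaic.shape)
        for k, (r0, c0) in enumerate(nominal[1:]):
            jr, jc = jitter[k]
            assert refined[k + 1] == (r0 + jr, c0 + jc)

    def test_featureless_tiles_fall_back_to_nominal(self):
        tiles = [np.ones((30, 30))] * 4
        nominal = [(0, 0), (0, 20), (20, 0), (20, 20)]
        with pytest.warns(UserWarning, match="nominal"):
            _, refined = stitch_tiles(tiles, nominal, (50, 50))
        assert refined == nominal


class TestBeadDetection:
    def test_fifty_sparse_spots_within_quarter_pixel(self, grid100):
        rng = np.random.default_rng(1)
        pts = []
        while len(pts) < 50:
            c = rng.uniform(30, 470, size=2)
            if not pts or min(np.hypot(*(c - p)) for p in pts) > 25:
                pts.append(c)
        pts = np.asarray(pts)
        cloud = detect_bead_centroids(render_beads(pts, grid100, 1.0), grid100)
        assert cloud.n_beads == 50
        d, _ = cKDTree(pts).query(cloud.coords_um)
        assert d.max() / grid100.pixel_size < 0.25

    def test_blank_image_gives_empty_cloud(self, grid100):
        cloud = detect_bead_centroids(np.zeros((100, 100)), grid100)
        assert cloud.n_beads == 0

    def test_nearby_spots_merge_to_one_detection(self, grid100):
        pts = np.array([[250.0, 250.0], [251.5, 250.0]])  # 1.5 µm apart
        cloud = detect_bead_centroids(render_beads(pts, grid100, 1.0), grid100)
        assert cloud.n_beads == 1

    def test_no_pair_closer_than_bead_diameter(self, bead_scene, grid100):
        _, img = bead_scene
        cloud = detect_bead_centroids(img, grid100)
        if cloud.n_beads > 1:
            d, _ = cKDTree(cloud.coords_um).query(cloud.coords_um, k=2)
            assert d[:, 1].min() > 2.0


class TestRigidTransform:
    @settings(max_examples=30, deadline=None)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
    )
    def test_apply_then_invert_is_identity(self, angle, tx, ty):
        t = RigidTransform(angle, np.array([tx, ty]))
        pts = np.array([[0.0, 0.0], [100.0, 50.0], [-30.0, 250.0]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_compose_order(self):
        a = RigidTransform(0.3, np.array([5.0, 0.0]))
        b = RigidTransform(-0.1, np.array([0.0, 2.0]))
        pts = np.array([[1.0, 2.0]])
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))


class TestICP:
    def test_self_registration_is_identity(self, bead_scene):
        pts, _ = bead_scene
        t = icp_rigid_register(BeadCloud(pts), BeadCloud(pts))
        assert abs(t.angle_rad) < 1e-9
        assert np.all(np.abs(t.translation_um) < 1e-9)

    def test_recovers_known_transform(self, bead_scene):
        pts, _ = bead_scene
        truth = RigidTransform(np.deg2rad(7.0), np.array([13.0, -5.0]))
        rec = icp_rigid_register(BeadCloud(pts), BeadCloud(truth.apply(pts)))
        assert rec.angle_rad == pytest.approx(truth.angle_rad, abs=1e-6)
        assert np.allclose(rec.translation_um, truth.translation_um, atol=1e-6)

    def test_robust_to_ten_percent_outliers(self, bead_scene):
        pts, _ = bead_scene
        truth = RigidTransform(np.deg2rad(7.0), np.array([13.0, -5.0]))
        rng = np.random.default_rng(3)
        moved = truth.apply(pts).copy()
        idx = rng.choice(len(pts), len(pts) // 10, replace=False)
        moved[idx] = rng.uniform(0, 500, size=(len(idx), 2))
        rec = icp_rigid_register(BeadCloud(pts), BeadCloud(moved))
        assert abs(np.rad2deg(rec.angle_rad - truth.angle_rad)) < 0.1
        assert np.all(np.abs(rec.translation_um - truth.translation_um) < 0.1)

    def test_degenerate_geometry_raises(self):
        line = np.column_stack([np.linspace(0, 100, 10), np.zeros(10)])
        with pytest.raises(PipelineError):
            icp_rigid_register(BeadCloud(line), BeadCloud(line))
        with pytest.raises(PipelineError):
            icp_rigid_register(BeadCloud(line[:2]), BeadCloud(line[:2]))


class TestNormalization:
    def test_constant_image(self):
        norm, peak = normalize_plate_intensity([np.full((50, 50), 3.0)])
        assert peak == pytest.approx(3.0)
        assert np.allclose(norm[0], 1.0)

    def test_peak_matches_sort_based_percentile_oracle(self):
        rng = np.random.default_rng(4)
        imgs = [rng.random((200, 200)) for _ in range(3)]
        imgs[1][:5, :5] = 50.0  # planted upper tail
        _, peak = normalize_plate_intensity(imgs)
        pooled = np.sort(np.concatenate([im.ravel() for im in imgs]))
        oracle = np.percentile(pooled, 99.99)
        assert peak == pytest.approx(oracle)

    def test_values_above_peak_clip_to_one(self):
        rng = np.random.default_rng(5)
        imgs = [rng.random((100, 100)), rng.random((100, 100)) * 2]
        norm, _ = normalize_plate_intensity(imgs)
        for im in norm:
            assert im.max() <= 1.0

    def test_idempotent_on_normalized_pool(self):
        rng = np.random.default_rng(6)
        imgs = [rng.random((100, 100)) for _ in range(2)]
        once, peak1 = normalize_plate_intensity(imgs)
        twice, peak2 = normalize_plate_intensity(once)
        # the re-derived peak is 1 (already scaled), so images are unchanged
        assert peak2 == pytest.approx(1.0, rel=1e-6)
        for a, b in zip(once, twice):
            assert np.allclose(a, b, atol=1e-9)

    def test_all_zero_input_raises(self):
        with pytest.raises(PipelineError):
            normalize_plate_intensity([np.zeros((10, 10))])


class TestSegmentation:
    @staticmethod
    def _disk_image(radius_px=30, value=0.8, background=0.05, shape=(100, 100)):
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        mask = (rr - shape[0] / 2) ** 2 + (cc - shape[1] / 2) ** 2 <= radius_px**2
        img = np.full(shape, background)
        img[mask] = value
        return img, mask

    def test_disk_recovered_with_high_dice(self):
        img, truth = self._disk_image()
        mask = segment_roi(img)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice > 0.98

    def test_background_only_gives_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = segment_roi(np.full((50, 50), 0.2))
        assert not mask.any()

    def test_largest_component_wins(self):
        img, _ = self._disk_image(radius_px=25)
        img[5:8, 5:8] = 0.9  # small distant debris blob
        mask = segment_roi(img)
        assert not mask[5:8, 5:8].any()
        assert mask[50, 50]

    def test_invariant_to_positive_scaling(self):
        img, _ = self._disk_image()
        assert np.array_equal(segment_roi(img), segment_roi(0.5 * img))


class TestFFDRegistration:
    def test_identical_images_give_zero_field(self, bead_scene, grid100):
        _, img = bead_scene
        field = ffd_register(img, img, grid100)
        assert np.abs(field.ux).max() < 1e-3
        assert np.abs(field.uy).max() < 1e-3

    def test_known_smooth_warp_subpixel_accuracy(self, bead_scene, grid100):
        pts, ref = bead_scene

        def warp(p):
            s = np.sin(np.pi * p[:, 0] / 500) * np.sin(np.pi * p[:, 1] / 500)
            return np.column_stack([8 * s, -6 * s])

        moving = render_beads(pts + warp(pts), grid100, 1.0)
        field = ffd_register(ref, moving, grid100)
        rc = grid100.to_pixel_indices(pts)
        ux = ndimage.map_coordinates(field.ux, [rc[:, 0], rc[:, 1]], order=1)
        uy = ndimage.map_coordinates(field.uy, [rc[:, 0], rc[:, 1]], order=1)
        true = warp(pts)
        mee = np.hypot(ux - true[:, 0], uy - true[:, 1]).mean()
        assert mee < 1.0  # one fifth of a pixel

    def test_pure_translation_recovered_as_constant_field(self, bead_scene, grid100):
        pts, ref = bead_scene
        shift = np.array([6.0, -4.0])
        moving = render_beads(pts + shift, grid100, 1.0)
        field = ffd_register(ref, moving, grid100)
        rc = grid100.to_pixel_indices(pts)
        ux = ndimage.map_coordinates(field.ux, [rc[:, 0], rc[:, 1]], order=1)
        uy = ndimage.map_coordinates(field.uy, [rc[:, 0], rc[:, 1]], order=1)
        mag = np.linalg.norm(shift)
        assert abs(ux.mean() - shift[0]) < 0.05 * mag
        assert abs(uy.mean() - shift[1]) < 0.05 * mag


class TestScatteredBSpline:
    def test_reproduces_smooth_function_at_and_between_samples(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 500, size=(400, 2))

        def f(p):
            return np.sin(p[:, 0] / 80.0) * np.cos(p[:, 1] / 100.0)

        surf = ScatteredBSplineField(pts, f(pts), (500.0, 500.0), levels=5)
        assert np.allclose(surf(pts), f(pts), atol=0.02)
        probe = rng.uniform(50, 450, size=(200, 2))
        assert np.abs(surf(probe) - f(probe)).max() < 0.05

    def test_vector_valued_fit_matches_componentwise(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 500, size=(100, 2))
        vals = np.column_stack([pts[:, 0] / 500.0, pts[:, 1] / 500.0])
        surf = ScatteredBSplineField(pts, vals, (500.0, 500.0))
        sx = ScatteredBSplineField(pts, vals[:, 0], (500.0, 500.0))
        out = surf(pts)
        assert np.allclose(out[:, 0], sx(pts))


class TestBeadDeformationField:
    def test_match_beads_rejects_inconsistent_pairs(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 500, size=(100, 2))
        disp = np.tile([1.0, 0.5], (100, 1))
        moved = pts + disp
        moved[0] += 12.0  # one bead jumps inconsistently
        ref, d = match_beads(BeadCloud(pts), BeadCloud(moved))
        assert len(ref) >= 90
        assert np.allclose(d, [1.0, 0.5], atol=1e-9)

    def test_recovers_smooth_warp_from_rendered_pair(self, bead_scene, grid100):
        pts, ref = bead_scene

        def warp(p):
            s = np.sin(np.pi * p[:, 0] / 500) * np.sin(np.pi * p[:, 1] / 500)
            return np.column_stack([4 * s, -3 * s])

        moving = render_beads(pts + warp(pts), grid100, 1.0)
        field = bead_deformation_field(ref, moving, grid100)
        rc = grid100.to_pixel_indices(pts)
        ux = ndimage.map_coordinates(field.ux, [rc[:, 0], rc[:, 1]], order=1)
        uy = ndimage.map_coordinates(field.uy, [rc[:, 0], rc[:, 1]], order=1)
        true = warp(pts)
        mee = np.hypot(ux - true[:, 0], uy - true[:, 1]).mean()
        assert mee < 0.5
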