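"""Contour closure, hole filling, star-convex splitting, size filtering."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from cyclecell import evalmetrics, postprocess, simgen
from cyclecell.postprocess import (LabelImage, close_tissue_contour,
                                   fill_small_holes, filter_by_area,
                                   labels_to_centers, split_star_convex)


def _ring_with_gap(shape=(64, 64), gap_halfwidth=5):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    r = np.hypot(yy - 32, xx - 32)
    ring = (r > 20) & (r < 23)
    ring[(np.abs(yy - 32) < gap_halfwidth) & (xx > 32)] = False
    return ring


def _leaks(binary, inside_point):
    """True if background floods from the border to ``inside_point``."""
    lab, _ = ndi.label(~binary)
    border = set(np.unique(np.concatenate(
        [lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
    return lab[inside_point] in border


class TestCloseTissueContour:
    def test_union_never_removes_foreground(self):
        ring = _ring_with_gap()
        closed = close_tissue_contour(ring)
        assert (closed & ring).sum() == ring.sum()

    def test_gapped_ring_sealed(self):
        ring = _ring_with_gap()
        assert _leaks(ring, (32, 32))
        closed = close_tissue_contour(ring)
        assert not _leaks(closed, (32, 32))

    def test_two_islands_two_closed_contours(self):
        img = np.zeros((128, 128), dtype=bool)
        for cy, cx in ((32, 32), (96, 96)):
            yy, xx = np.mgrid[:128, :128]
            r = np.hypot(yy - cy, xx - cx)
            ring = (r > 14) & (r < 17)
            ring[(np.abs(yy - cy) < 4) & (xx > cx)] = False  # 8 px gap
            img |= ring
        closed = close_tissue_contour(img)
        assert not _leaks(closed, (32, 32))
        assert not _leaks(closed, (96, 96))
        # islands stay separate
        _, n = ndi.label(closed)
        assert n == 2

    def test_fewer_than_three_points_warns_and_passes_through(self):
        img = np.zeros((32, 32), dtype=bool)
        img[5, 5] = True
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = close_tissue_contour(img)
        assert len(rec) == 1
        np.testing.assert_array_equal(out, img)

    def test_closed_ring_stays_closed(self):
        yy, xx = np.mgrid[:64, :64]
        r = np.hypot(yy - 32, xx - 32)
        ring = (r > 20) & (r < 23)
        closed = close_tissue_contour(ring)
        assert not _leaks(closed, (32, 32))
        assert (closed & ring).sum() == ring.sum()


class TestFillSmallHoles:
    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32)) > 0.5
        np.testing.assert_array_equal(fill_small_holes(img, 0), img)

    def test_small_hole_filled_large_kept(self):
        img = np.ones((40, 40), dtype=bool)
        img[5:7, 5:8] = False          # 6 px hole < 40
        img[20:30, 20:30] = False      # 100 px interior >= 40
        out = fill_small_holes(img, 40)
        assert out[5:7, 5:8].all()
        assert not out[20:30, 20:30].any()

    def test_border_touching_background_never_filled(self):
        img = np.ones((20, 20), dtype=bool)
        img[0:2, 9:11] = False  # 4 px notch at the border
        out = fill_small_holes(img, 40)
        assert not out[0, 9]

    def test_strictly_smaller_than_threshold(self):
        img = np.ones((20, 20), dtype=bool)
        img[8:10, 8:13] = False  # exactly 10 px
        assert not fill_small_holes(img, 10)[8, 8]
        assert fill_small_holes(img, 11)[8, 8]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48)) > 0.4
        once = fill_small_holes(img, 30)
        twice = fill_small_holes(once, 30)
        np.testing.assert_array_equal(once, twice)


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return np.hypot(yy - cy, xx - cx) <= r


def _outline(mask):
    return mask & ~ndi.binary_erosion(mask)


class TestSplitStarConvex:
    def test_two_disjoint_disks(self):
        m = _disk_mask((80, 80), 20, 20, 12) | _disk_mask((80, 80), 58, 58, 12)
        out = split_star_convex(_outline(m), expected_radius=8)
        assert out.n_instances == 2

    def test_dumbbell_split_into_two(self):
        """Two overlapping disks with centers 1.5 radii apart."""
        r = 12
        m = _disk_mask((80, 80), 40, 28, r) | _disk_mask((80, 80), 40, 46, r)
        out = split_star_convex(_outline(m), expected_radius=8)
        assert out.n_instances == 2

    def test_instances_star_convex_by_ray_casting(self, honeycomb_sample):
        """Brute-force: every instance pixel sees its instance center."""
        out = split_star_convex(honeycomb_sample.binary, expected_radius=8)
        assert out.n_instances > 10
        lab = out.labels
        checked = 0
        for idx in range(1, min(out.n_instances, 30) + 1):
            region = lab == idx
            com = ndi.center_of_mass(region)
            cy, cx = com
            if not region[int(round(cy)), int(round(cx))]:
                continue
            tol = ndi.binary_dilation(region, iterations=1)
            rr, cc = np.nonzero(region)
            for y, x in zip(rr[::5], cc[::5]):
                steps = int(max(abs(y - cy), abs(x - cx)) * 2) + 1
                ts = np.linspace(0, 1, steps)
                ys = np.round(cy + ts * (y - cy)).astype(int)
                xs = np.round(cx + ts * (x - cx)).astype(int)
                assert tol[ys, xs].all()
            checked += 1
        assert checked >= 10

    def test_instances_disjoint_and_inside_tissue(self, honeycomb_sample):
        closed = honeycomb_sample.binary
        out = split_star_convex(closed, expected_radius=8)
        tissue = ndi.binary_fill_holes(closed)
        assert not (out.labels > 0)[~tissue].any()
        assert not ((out.labels > 0) & closed).any()

    def test_empty_interior_zero_instances(self):
        out = split_star_convex(np.zeros((32, 32), dtype=bool))
        assert out.n_instances == 0

    def test_pretrained_backend_requires_model(self):
        m = _outline(_disk_mask((40, 40), 20, 20, 10))
        with pytest.raises(RuntimeError):
            split_star_convex(m, backend="pretrained")

    def test_pretrained_backend_delegates(self):
        m = _outline(_disk_mask((40, 40), 20, 20, 10))

        class Stub:
            def predict_instances(self, mask):
                lab, _ = ndi.label(mask)
                return lab

        out = split_star_convex(m, backend="pretrained", model=Stub())
        assert out.n_instances == 1


class TestFilterByArea:
    def _labels_with_areas(self, areas):
        img = np.zeros((64, len(areas) * 16), dtype=np.int32)
        for i, a in enumerate(areas):
            rows = a // 8
            rem = a % 8
            c0 = i * 16
            img[:rows, c0:c0 + 8] = i + 1
            if rem:
                img[rows, c0:c0 + rem] = i + 1
        return LabelImage(labels=img, n_instances=len(areas))

    def test_sg_threshold_100(self):
        out = filter_by_area(self._labels_with_areas([99, 100, 150]), "SG")
        assert out.n_instances == 2

    def test_ss_threshold_50(self):
        out = filter_by_area(self._labels_with_areas([49, 50, 30]), "SS")
        assert out.n_instances == 1

    def test_labels_recompacted(self):
        out = filter_by_area(self._labels_with_areas([49, 60, 20, 70]), "SS")
        assert sorted(np.unique(out.labels)) == [0, 1, 2]

    def test_empty_input(self):
        out = filter_by_area(LabelImage(np.zeros((8, 8), np.int32), 0), "SG")
        assert out.n_instances == 0

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            filter_by_area(LabelImage(np.zeros((8, 8), np.int32), 0), "SB")


class TestLabelsToCenters:
    def test_square_centroid(self):
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[0:3, 0:3] = 1
        pts = labels_to_centers(LabelImage(lab, 1)).points
        np.testing.assert_allclose(pts, [[1.0, 1.0]])

    def test_one_point_per_instance(self, honeycomb_sample):
        out = split_star_convex(honeycomb_sample.binary, expected_radius=8)
        pts = labels_to_centers(out).points
        assert len(pts) == out.n_instances

    def test_l_shape_centroid_matches_pixel_mean(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:8, 2:4] = 1
        lab[6:8, 4:9] = 1
        pts = labels_to_centers(LabelImage(lab, 1)).points
        expected = np.argwhere(lab == 1).mean(axis=0)
        np.testing.assert_allclose(pts[0], expected)


def test_dropout_recovery_single_replicate():
    """One seeded 20%-dropout replicate through the full chain scores high."""
    s = simgen.generate_training_sample(rng_seed=77, index=0)
    rng = np.random.default_rng(0)
    binary = s.binary.copy()
    fg = np.argwhere(binary)
    drop = fg[rng.random(len(fg)) < 0.2]
    binary[drop[:, 0], drop[:, 1]] = False
    closed = close_tissue_contour(binary)
    filled = fill_small_holes(closed, 40)
    labels = filter_by_area(split_star_convex(filled, expected_radius=8), "SS")
    pred = labels_to_centers(labels)
    r = evalmetrics.match_detections(pred, s.centers.points, d=10.0)
    assert r.f1 >= 0.8
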