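"""Morphology chain stages versus naive brute-force reference implementations."""

import numpy as np
import pytest

from eagleseg.morphology import (
    MorphologyConfig,
    canny_edges,
    dilate,
    fill_holes,
    postprocess,
    remove_small_regions,
    select_region,
    trace_boundaries,
)


# ---------------------------------------------------------------- naive oracles
def naive_dilate(mask, radius):
    """Pairwise pixel-distance Minkowski dilation by a Euclidean disk."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    pts = np.argwhere(mask)
    for y in range(h):
        for x in range(w):
            if pts.size and np.min((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2) <= radius**2:
                out[y, x] = 1
    return out


def naive_components(mask, connectivity=8):
    """Flood-fill connected-component labeling."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    cur = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not labels[sy, sx]:
                cur += 1
                stack = [(sy, sx)]
                labels[sy, sx] = cur
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not labels[ny, nx]:
                            labels[ny, nx] = cur
                            stack.append((ny, nx))
    return labels, cur


def naive_fill_holes(mask):
    """Flood the background from the border (4-adjacency); unfilled -> holes."""
    inv = 1 - mask
    labels, n = naive_components(inv, connectivity=4)
    border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab not in border_labels:
            out[labels == lab] = 1
    return out


def naive_remove_small(mask, min_area, connectivity=8):
    labels, n = naive_components(mask, connectivity)
    out = mask.copy()
    for lab in range(1, n + 1):
        if np.sum(labels == lab) < min_area:
            out[labels == lab] = 0
    return out


def random_masks(count, shape=(32, 32), density=0.35, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(count):
        yield (rng.random(shape) < density).astype(np.uint8)


# --------------------------------------------------------------------- stages
class TestCannyEdges:
    def test_flat_masks_have_no_edges(self):
        assert canny_edges(np.zeros((20, 20), dtype=np.uint8)).sum() == 0
        assert canny_edges(np.ones((20, 20), dtype=np.uint8)).sum() == 0

    def test_square_yields_closed_loop_near_perimeter(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[22:42, 22:42] = 1
        edges = canny_edges(mask)
        assert edges.sum() > 0
        # every edge pixel within 2 px of the analytic perimeter set
        per = np.zeros_like(mask)
        per[22:42, 22:42] = 1
        per[23:41, 23:41] = 0
        py, px = np.nonzero(per)
        for y, x in np.argwhere(edges):
            assert np.min((py - y) ** 2 + (px - x) ** 2) <= 4
        # closed loop: edge map encloses at least the square's interior core
        filled = fill_holes(edges)
        assert filled[31, 31] == 1


class TestDilate:
    def test_empty_stays_empty(self):
        assert dilate(np.zeros((8, 8), dtype=np.uint8), 1).sum() == 0

    def test_single_pixel_radius1_is_plus_shape(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        out = dilate(mask, 1)
        expected = np.zeros_like(mask)
        expected[2, 1:4] = 1
        expected[1:4, 2] = 1
        np.testing.assert_array_equal(out, expected)

    def test_extensive(self):
        for mask in random_masks(5, seed=3):
            out = dilate(mask, 2)
            assert np.all(out >= mask)

    def test_matches_naive_pairwise_distance(self):
        for mask in random_masks(10, shape=(16, 16), density=0.15, seed=5):
            for radius in (1, 2):
                np.testing.assert_array_equal(dilate(mask, radius), naive_dilate(mask, radius))


class TestTraceBoundaries:
    def test_two_squares_two_closed_boundaries(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:7, 2:7] = 1
        mask[10:16, 10:16] = 1
        labels, bounds = trace_boundaries(mask)
        assert labels.max() == 2
        assert len(bounds) == 2

    def test_empty_mask_no_components(self):
        labels, bounds = trace_boundaries(np.zeros((5, 5), dtype=np.uint8))
        assert labels.max() == 0 and bounds == {}

    def test_3x3_square_boundary_is_its_8_outer_pixels(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        _, bounds = trace_boundaries(mask)
        boundary = bounds[1]
        assert len(boundary) == 8
        assert (3, 3) not in boundary  # center excluded
        assert set(boundary) == {(y, x) for y in range(2, 5) for x in range(2, 5)} - {(3, 3)}
        # consecutive boundary pixels are 8-adjacent (a closed traversal)
        closed = boundary + [boundary[0]]
        for (y0, x0), (y1, x1) in zip(closed, closed[1:]):
            assert max(abs(y0 - y1), abs(x0 - x1)) == 1


class TestRemoveSmall:
    def test_zero_min_area_identity(self):
        for mask in random_masks(3, seed=7):
            np.testing.assert_array_equal(remove_small_regions(mask, 0), mask)

    def test_size_filter(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[1:3, 1:3] = 1  # 4 px, removed at min_area 5
        mask[6:16, 6:16] = 1  # 100 px survives
        out = remove_small_regions(mask, 5)
        assert out[2, 2] == 0 and out[10, 10] == 1

    def test_components_of_sizes_3_and_50(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[0, 0:3] = 1
        mask[5:10, 5:15] = 1
        out = remove_small_regions(mask, 4)
        _, n = naive_components(out)
        assert n == 1 and out.sum() == 50

    def test_matches_naive(self):
        for mask in random_masks(10, density=0.25, seed=9):
            for min_area in (2, 5):
                np.testing.assert_array_equal(
                    remove_small_regions(mask, min_area), naive_remove_small(mask, min_area)
                )

    def test_idempotent(self):
        for mask in random_masks(5, seed=11):
            once = remove_small_regions(mask, 4)
            np.testing.assert_array_equal(once, remove_small_regions(once, 4))


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        yy, xx = np.ogrid[:21, :21]
        disk = (((yy - 10) ** 2 + (xx - 10) ** 2) <= 49).astype(np.uint8)
        np.testing.assert_array_equal(fill_holes(disk), disk)

    def test_ring_becomes_disk(self):
        yy, xx = np.ogrid[:31, :31]
        r2 = (yy - 15) ** 2 + (xx - 15) ** 2
        ring = ((r2 <= 100) & (r2 >= 64)).astype(np.uint8)
        filled = fill_holes(ring)
        disk = (r2 <= 100).astype(np.uint8)
        np.testing.assert_array_equal(filled, disk)

    def test_border_touching_background_never_filled(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 1
        filled = fill_holes(mask)
        np.testing.assert_array_equal(filled, mask)

    def test_matches_naive_border_flood(self):
        for mask in random_masks(10, density=0.45, seed=13):
            np.testing.assert_array_equal(fill_holes(mask), naive_fill_holes(mask))

    def test_idempotent(self):
        for mask in random_masks(5, density=0.45, seed=15):
            once = fill_holes(mask)
            np.testing.assert_array_equal(once, fill_holes(once))


class TestSelectRegion:
    def test_single_component_unchanged(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        np.testing.assert_array_equal(select_region(mask), mask)

    def test_largest_kept(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[0:4, 0:10] = 1  # 40
        mask[10:20, 0:10] = 1  # 100
        out = select_region(mask)
        assert out.sum() == 100 and out[12, 5] == 1

    def test_tie_broken_by_raster_order(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[1:6, 12:17] = 1  # raster-first (row 1)
        mask[8:13, 1:6] = 1
        out = select_region(mask)
        assert out[2, 13] == 1 and out[10, 2] == 0

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = select_region(np.zeros((5, 5), dtype=np.uint8))
        assert out.sum() == 0

    def test_all_mode_identity(self):
        for mask in random_masks(3, seed=17):
            np.testing.assert_array_equal(select_region(mask, selection="all"), mask)


class TestPostprocess:
    def test_disk_plus_specks_recovers_disk(self):
        rng = np.random.default_rng(23)
        mask = np.zeros((64, 64), dtype=np.uint8)
        yy, xx = np.ogrid[:64, :64]
        disk = ((yy - 32) ** 2 + (xx - 40) ** 2) <= 144
        mask[disk] = 1
        for _ in range(5):  # scattered 2-px specks
            y, x = rng.integers(2, 20, size=2)
            mask[y, x] = mask[y, x + 1] = 1
        out = postprocess(mask, MorphologyConfig(min_area=50))
        np.testing.assert_array_equal(out, disk.astype(np.uint8))

    def test_empty_mask_warns_and_stays_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            out = postprocess(np.zeros((32, 32), dtype=np.uint8))
        assert out.sum() == 0

    def test_single_component_output_contract(self):
        for mask in random_masks(5, shape=(48, 48), density=0.4, seed=29):
            out = postprocess(mask, MorphologyConfig(min_area=10))
            _, n = naive_components(out)
            assert n == 1

    def test_no_far_field_pixels(self):
        # output within the filled dilation of the input (plus input itself)
        for mask in random_masks(5, shape=(40, 40), density=0.3, seed=31):
            out = postprocess(mask, MorphologyConfig(min_area=5))
            envelope = naive_fill_holes(dilate(mask, 2)) | mask
            assert np.all(out <= envelope)

    def test_return_stages_products(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        region, stages = postprocess(mask, MorphologyConfig(min_area=5), return_stages=True)
        assert set(stages) >= {"edges", "closed_edges", "labels", "boundaries", "cleaned", "filled"}
        assert region.sum() == 256


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"canny_sigma": 0.0},
            {"canny_low": 0.3, "canny_high": 0.2},
            {"dilation_radius": 0},
            {"connectivity": 6},
            {"selection": "biggest"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MorphologyConfig(**kwargs).validate()
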