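"""Map construction and metrics: normalisation, thresholding, CoG, overlap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from backmap.grid import GridSpec, default_grid
from backmap.mapping import (
    average_group_map,
    build_map,
    cog,
    cog_variation,
    cog_vector,
    map_area,
    map_overlap,
    map_volume,
)

GRID = default_grid()


def amplitude_grid(entries, default=0.0):
    """(row, col) -> value dict to a full 8 x 5 array."""
    arr = np.full(GRID.shape, default)
    for (r, c), v in entries.items():
        arr[r, c] = v
    return arr


# --- independent straight-loop oracle ---------------------------------------

def loop_metrics(amplitudes, threshold=0.25):
    """Brute-force re-implementation with explicit loops over sites."""
    peak = max(max(row) for row in amplitudes.tolist())
    if peak <= 0:
        return None
    sx = sy = sz = 0.0
    volume = 0.0
    area = 0
    active = [[False] * GRID.n_cols for _ in range(GRID.n_rows)]
    for r in range(GRID.n_rows):
        for c in range(GRID.n_cols):
            z = amplitudes[r, c] / peak
            if z < threshold:
                continue
            active[r][c] = True
            area += 1
            volume += z
            sx += z * GRID.x_coords[c]
            sy += z * GRID.y_coords[r]
            sz += z
    return {"cog": (sx / sz, sy / sz), "volume": volume, "area": area, "active": active}


def loop_overlap(active_a, active_b):
    inter = union = 0
    for r in range(GRID.n_rows):
        for c in range(GRID.n_cols):
            a, b = active_a[r][c], active_b[r][c]
            inter += a and b
            union += a or b
    return inter / union if union else 0.0


class TestBuildMap:
    def test_threshold_removal(self):
        arr = amplitude_grid({(0, 0): 4.0, (0, 1): 2.0, (0, 2): 0.9})
        m = build_map(arr, GRID)
        assert m.z[0, 0] == 1.0 and m.z[0, 1] == 0.5 and m.z[0, 2] == 0.0
        assert map_area(m) == 2  # 0.9/4 = 0.225 < 0.25 removed
        assert m.raw_peak_uV == 4.0

    def test_all_equal_all_active(self):
        m = build_map(np.full(GRID.shape, 7.0), GRID)
        assert np.all(m.z == 1.0)
        assert map_area(m) == 40

    def test_exact_threshold_site_kept(self):
        arr = amplitude_grid({(0, 0): 100.0, (3, 2): 25.0})
        m = build_map(arr, GRID)
        assert m.active_mask[3, 2]
        assert map_area(m) == 2

    def test_all_zero_returns_inactive_map(self):
        m = build_map(np.zeros(GRID.shape), GRID)
        assert not m.any_active
        assert map_volume(m) == 0.0 and map_area(m) == 0
        with pytest.raises(ValueError, match="undefined"):
            cog(m)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            build_map(np.zeros((4, 4)), GRID)


class TestCog:
    def test_single_active_site(self):
        m = build_map(amplitude_grid({(3, 2): 50.0}), GRID)
        assert cog(m) == pytest.approx((2.0, 1.0))

    def test_symmetric_pair(self):
        row = list(GRID.y_coords).index(0.0)
        m = build_map(amplitude_grid({(row, 1): 5.0, (row, 3): 5.0}), GRID)
        assert cog(m) == pytest.approx((2.0, 0.0))

    def test_hand_weighted_centroid(self):
        # z = {(0,0): 1, (1,0): 0.5, (0,1): 0.5} in (x, y) cm at the origin rows
        r0 = list(GRID.y_coords).index(0.0)
        r1 = list(GRID.y_coords).index(1.0)
        m = build_map(amplitude_grid({(r0, 0): 1.0, (r0, 1): 0.5, (r1, 0): 0.5}), GRID)
        assert cog(m) == pytest.approx((0.25, 0.25))

    @given(
        hnp.arrays(float, (8, 5), elements=st.floats(0, 100)),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, arr, factor):
        """CoG (and the whole normalised map) ignores multiplicative gain."""
        if arr.max() <= 0:
            return
        m1 = build_map(arr, GRID)
        m2 = build_map(arr * factor, GRID)
        np.testing.assert_allclose(m1.z, m2.z, atol=1e-12)
        if m1.any_active:
            assert cog(m1) == pytest.approx(cog(m2))


class TestVectorVolumeArea:
    @pytest.mark.parametrize("xy,expected", [((3.0, 4.0), 5.0), ((0.0, 0.0), 0.0),
                                             ((2.35, 1.50), 2.7879)])
    def test_cog_vector(self, xy, expected):
        assert cog_vector(xy) == pytest.approx(expected, abs=1e-4)

    def test_volume_sums_normalised(self):
        m = build_map(amplitude_grid({(0, 0): 10.0, (0, 1): 5.0, (0, 2): 3.0}), GRID)
        assert map_volume(m) == pytest.approx(1.8)

    def test_single_site_volume_one(self):
        m = build_map(amplitude_grid({(2, 2): 42.0}), GRID)
        assert map_volume(m) == 1.0 and map_area(m) == 1

    def test_flat_map_upper_bound(self):
        m = build_map(np.full(GRID.shape, 1.0), GRID)
        assert map_volume(m) == 40.0

    @given(hnp.arrays(float, (8, 5), elements=st.floats(0, 100)))
    def test_area_volume_consistency(self, arr):
        m = build_map(arr, GRID)
        area, volume = map_area(m), map_volume(m)
        assert (area == 0) == (volume == 0.0) == (not m.any_active)
        if area:
            assert 1.0 <= volume <= 40.0
            assert 0.25 * area <= volume <= area


class TestOverlap:
    def test_identical_masks(self):
        m = build_map(amplitude_grid({(0, 0): 9, (0, 1): 9, (1, 0): 9, (1, 1): 9, (2, 2): 9}), GRID)
        assert map_overlap(m, m).overlap == 1.0

    def test_disjoint_masks(self):
        a = build_map(amplitude_grid({(0, 0): 9}), GRID)
        b = build_map(amplitude_grid({(7, 4): 9}), GRID)
        assert map_overlap(a, b).overlap == 0.0

    def test_jaccard_formula(self):
        a = build_map(amplitude_grid({(0, c): 9 for c in range(4)}), GRID)
        b = build_map(amplitude_grid({(0, 2): 9, (0, 3): 9, (1, 0): 9, (1, 1): 9}), GRID)
        assert map_overlap(a, b).overlap == pytest.approx(2 / 6)

    def test_both_empty_defined_zero(self):
        e = build_map(np.zeros(GRID.shape), GRID)
        assert map_overlap(e, e).overlap == 0.0

    def test_grid_mismatch_rejected(self):
        other = GridSpec(x_coords=(0.0, 1.0, 2.0, 3.0, 4.5))
        a = build_map(np.ones(GRID.shape), GRID)
        b = build_map(np.ones(other.shape), other)
        with pytest.raises(ValueError, match="grid"):
            map_overlap(a, b)

    @given(
        hnp.arrays(float, (8, 5), elements=st.floats(0, 10)),
        hnp.arrays(float, (8, 5), elements=st.floats(0, 10)),
    )
    def test_symmetry_and_bounds(self, xa, xb):
        a, b = build_map(xa, GRID), build_map(xb, GRID)
        o1, o2 = map_overlap(a, b).overlap, map_overlap(b, a).overlap
        assert o1 == o2
        assert 0.0 <= o1 <= 1.0
        if a.any_active and np.array_equal(a.active_mask, b.active_mask):
            assert o1 == 1.0


class TestCogVariation:
    def test_identical_cogs_zero_deviation(self):
        devs, summary = cog_variation([(2.0, 1.0)] * 4)
        assert all(d.dev_vector == 0.0 for d in devs)
        assert summary["dev_vector"][0] == 0.0

    def test_hand_geometry(self):
        devs, summary = cog_variation([(1.0, 1.0), (3.0, 3.0)])
        for d in devs:
            assert d.dev_x == pytest.approx(1.0)
            assert d.dev_y == pytest.approx(1.0)
            assert d.dev_vector == pytest.approx(np.sqrt(2.0))
        assert summary["dev_vector"][0] == pytest.approx(np.sqrt(2.0))

    def test_single_cog_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cog_variation([(1.0, 1.0)])

    @given(st.lists(st.tuples(st.floats(0, 4), st.floats(-2, 5)), min_size=2, max_size=12))
    def test_deviation_triangle_bounds(self, cogs):
        devs, _ = cog_variation(cogs)
        for d in devs:
            assert d.dev_vector <= d.dev_x + d.dev_y + 1e-12
            assert d.dev_vector >= max(d.dev_x, d.dev_y) - 1e-12


class TestAverageGroupMap:
    def test_single_map_identity(self):
        m = build_map(amplitude_grid({(0, 0): 9, (1, 1): 5}), GRID)
        np.testing.assert_array_equal(average_group_map([m]), m.z)

    def test_shared_hotspot_peak_one(self):
        a = build_map(amplitude_grid({(2, 2): 10, (2, 3): 5}), GRID)
        b = build_map(amplitude_grid({(2, 2): 80, (3, 2): 30}), GRID)
        avg = average_group_map([a, b])
        assert avg[2, 2] == 1.0

    def test_different_hotspots_flatten(self):
        a = build_map(amplitude_grid({(0, 0): 10}), GRID)
        b = build_map(amplitude_grid({(5, 3): 10}), GRID)
        avg = average_group_map([a, b])
        assert avg[0, 0] == 0.5 and avg[5, 3] == 0.5
        assert avg.max() == 0.5


class TestLoopOracle:
    def test_random_tables_agree_with_loops(self, rng):
        for _ in range(100):
            arr = rng.uniform(0, 50, GRID.shape)
            m = build_map(arr, GRID)
            ref = loop_metrics(arr)
            assert cog(m) == pytest.approx(ref["cog"], abs=1e-12)
            assert map_volume(m) == pytest.approx(ref["volume"], abs=1e-12)
            assert map_area(m) == ref["area"]

    def test_overlap_agrees_with_loops(self, rng):
        for _ in range(50):
            xa, xb = rng.uniform(0, 50, (2, *GRID.shape))
            a, b = build_map(xa, GRID), build_map(xb, GRID)
            ra, rb = loop_metrics(xa), loop_metrics(xb)
            assert map_overlap(a, b).overlap == pytest.approx(
                loop_overlap(ra["active"], rb["active"]), abs=1e-15
            )
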