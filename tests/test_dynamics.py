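"""Range dynamics: classification, areas, change maps, centroids, stacking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entniche as en
from entniche.dynamics import CHANGE_NAMES, total_valid_area
from entniche.grids import GridSpec, Raster


@pytest.fixture
def grid():
    return GridSpec(west=100.0, north=25.0, cell_size=2.5, n_rows=30, n_cols=30)


def suitability(grid, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.uniform(size=grid.shape)
    v[0, 0] = np.nan
    return Raster(grid, v)


class TestClassify:
    @pytest.mark.parametrize("value,cls", [
        (0.05, 0), (0.1, 1), (0.29, 1), (0.30, 2), (0.49, 2), (0.5, 3), (1.0, 3), (0.0, 0),
    ])
    def test_bin_boundaries_belong_upward(self, grid, value, cls):
        r = Raster(grid, np.full(grid.shape, value))
        assert en.classify_suitability(r).values[5, 5] == cls

    def test_nodata_preserved_and_out_of_range_rejected(self, grid):
        s = suitability(grid)
        cm = en.classify_suitability(s)
        assert np.isnan(cm.values[0, 0])
        bad = Raster(grid, np.full(grid.shape, 1.5))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            en.classify_suitability(bad)

    def test_binary_at_half_equals_high_class(self, grid):
        s = suitability(grid, seed=3)
        via_class = en.classify_suitability(s).values == 3
        via_binary = en.to_binary(s, 0.5).values == 1
        assert np.array_equal(via_class, via_binary)

    def test_binary_threshold_conventions(self, grid):
        r = Raster(grid, np.full(grid.shape, 0.5))
        assert np.all(en.to_binary(r, 0.5).values == 1.0)
        low = Raster(grid, np.full(grid.shape, 0.05))
        assert np.all(en.to_binary(low, 0.1).values == 0.0)
        with pytest.raises(ValueError):
            en.to_binary(r, 1.5)


class TestAreas:
    def test_classes_partition_total_area(self, grid):
        cm = en.classify_suitability(suitability(grid, 5))
        areas = en.class_areas(cm)
        assert sum(areas.values()) == pytest.approx(total_valid_area(cm), rel=1e-12)

    def test_area_weighting_uses_latitude(self):
        northern = GridSpec(0.0, 60.0, 2.5, 1, 1)
        tropical = GridSpec(0.0, 0.5, 2.5, 1, 1)
        a_n = en.class_areas(Raster(northern, np.ones((1, 1))))[1]
        a_t = en.class_areas(Raster(tropical, np.ones((1, 1))))[1]
        assert a_n < a_t


class TestChangeMap:
    def test_identical_maps_have_no_expansion_or_contraction(self, grid):
        b = en.to_binary(suitability(grid, 1), 0.5)
        _, areas = en.change_map(b, b)
        assert areas["expansion"] == 0.0 and areas["contraction"] == 0.0

    def test_complementary_maps_have_no_stable(self, grid):
        b = en.to_binary(suitability(grid, 2), 0.5)
        flipped = b.copy_with(np.where(b.valid, 1 - b.values, np.nan))
        _, areas = en.change_map(b, flipped)
        assert areas["stable"] == 0.0 and areas["absent"] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation_identity_on_random_pairs(self, seed):
        g = GridSpec(100.0, 25.0, 2.5, 15, 15)
        rng = np.random.default_rng(seed)
        b = Raster(g, (rng.random(g.shape) < 0.5).astype(float))
        a = Raster(g, (rng.random(g.shape) < 0.5).astype(float))
        cm, areas = en.change_map(b, a)
        before_area = en.class_areas(b).get(1, 0.0)
        assert areas["stable"] + areas["contraction"] == pytest.approx(before_area, rel=1e-12)
        assert sum(areas.values()) == pytest.approx(total_valid_area(cm), rel=1e-12)

    def test_mismatched_grids_rejected(self, grid):
        other = GridSpec(0.0, 1.0, 2.5, 30, 30)
        b = Raster(grid, np.ones(grid.shape))
        a = Raster(other, np.ones(other.shape))
        with pytest.raises(ValueError):
            en.change_map(b, a)


class TestCentroid:
    def test_two_equal_latitude_cells_average(self):
        g = GridSpec(9.0, 21.0, 60.0, 3, 5)  # 1-degree cells
        v = np.zeros(g.shape)
        # centers at (10.5E, 19.5N) and (12.5E, 19.5N)
        v[1, 1] = 1
        v[1, 3] = 1
        c = en.centroid(Raster(g, v))
        assert c.lon == pytest.approx(11.5)
        assert c.lat == pytest.approx(19.5)

    def test_single_cell_is_its_center(self, grid):
        v = np.zeros(grid.shape)
        v[7, 9] = 1
        c = en.centroid(Raster(grid, v))
        lon, lat = grid.cell_center(7, 9)
        assert (c.lon, c.lat) == (pytest.approx(float(lon)), pytest.approx(float(lat)))

    def test_one_degree_shift_at_equator(self):
        assert en.great_circle_km(10.0, 0.0, 11.0, 0.0) == pytest.approx(111.195, abs=1e-3)
        from entniche.dynamics import initial_bearing_deg
        assert initial_bearing_deg(10.0, 0.0, 11.0, 0.0) == pytest.approx(90.0)

    def test_symmetric_range_centroid_on_meridian(self):
        g = GridSpec(100.0, 25.0, 2.5, 21, 21)
        v = np.zeros(g.shape)
        mid = 10
        for dr, dc in [(0, 0), (3, 4), (3, -4), (-5, 2), (-5, -2)]:
            v[mid + dr, mid + dc] = 1
        c = en.centroid(Raster(g, v))
        lon_mid, _ = g.cell_center(mid, mid)
        assert c.lon == pytest.approx(float(lon_mid))

    def test_empty_range_rejected(self, grid):
        with pytest.raises(ValueError, match="empty"):
            en.centroid(Raster(grid, np.zeros(grid.shape)))

    def test_centroid_within_bounding_box(self, grid):
        rng = np.random.default_rng(9)
        v = (rng.random(grid.shape) < 0.2).astype(float)
        c = en.centroid(Raster(grid, v))
        rows, cols = np.nonzero(v == 1)
        lon, lat = grid.cell_center(rows, cols)
        assert lon.min() <= c.lon <= lon.max()
        assert lat.min() <= c.lat <= lat.max()


class TestStacking:
    def test_overlap_counts_and_max_cell(self, grid):
        maps = {}
        for i, sp in enumerate("abc"):
            v = np.zeros(grid.shape)
            v[5, 5] = 1          # shared cell
            v[10 + i, 2] = 1     # disjoint cells
            maps[sp] = Raster(grid, v)
        counts, mx, cells = en.stack_species(maps)
        assert mx == 3 and (5, 5) in cells and len(cells) == 1

    def test_disjoint_ranges_max_one(self, grid):
        maps = {}
        for i, sp in enumerate("ab"):
            v = np.zeros(grid.shape)
            v[i, i] = 1
            maps[sp] = Raster(grid, v)
        _, mx, _ = en.stack_species(maps)
        assert mx == 1

    def test_area_weighted_double_counting_identity(self, grid):
        rng = np.random.default_rng(11)
        maps = {sp: Raster(grid, (rng.random(grid.shape) < 0.3).astype(float))
                for sp in "abcd"}
        counts, _, _ = en.stack_species(maps)
        area = grid.area_raster()
        lhs = float(np.nansum(counts.values * area))
        rhs = sum(en.class_areas(m).get(1, 0.0) for m in maps.values())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestRefugium:
    def test_intersection_properties(self, grid):
        rng = np.random.default_rng(12)
        lgm = Raster(grid, (rng.random(grid.shape) < 0.4).astype(float))
        cur = Raster(grid, (rng.random(grid.shape) < 0.4).astype(float))
        ref = en.infer_refugium(lgm, cur)
        present = ref.values == 1
        assert np.all(lgm.values[present] == 1)
        assert np.all(cur.values[present] == 1)
        same = en.infer_refugium(lgm, lgm)
        assert np.array_equal(same.values, lgm.values)
        empty = en.infer_refugium(lgm, lgm.copy_with(1 - lgm.values))
        assert np.nansum(empty.values) == 0
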