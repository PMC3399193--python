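import numpy as np
import pandas as pd
import pytest

from rangeshift.dispersal import (
    BinaryRange,
    apply_scenario,
    binarize,
    build_masks,
    realistic_scenario,
    realized_from_potential,
)
from rangeshift.errors import InvalidParameterError, MissingDataError, SchemaError
from rangeshift.grids import GridSpec
from rangeshift.maxent import SuitabilityMap
from rangeshift.synth import RegionMosaic, SpeciesMeta


def _range(presence, grid, **kw):
    presence = np.asarray(presence, dtype=bool)
    return BinaryRange(presence=presence, valid=np.ones_like(presence, dtype=bool),
                       grid=grid, **kw)


class TestBinarize:
    def test_equal_and_greater_is_presence(self):
        grid = GridSpec(1, 3)
        smap = SuitabilityMap(values=np.array([[0.49, 0.5, 0.51]]), grid=grid)
        br = binarize(smap, 0.5)
        np.testing.assert_array_equal(br.presence, [[False, True, True]])

    def test_threshold_above_max_empties_range(self):
        grid = GridSpec(2, 2)
        smap = SuitabilityMap(values=np.full(grid.shape, 0.3), grid=grid)
        assert binarize(smap, 0.9).n_cells == 0

    def test_threshold_at_or_below_min_keeps_all(self):
        grid = GridSpec(2, 2)
        smap = SuitabilityMap(values=np.full(grid.shape, 0.3), grid=grid)
        assert binarize(smap, 0.1).n_cells == 4

    def test_nodata_never_present(self):
        grid = GridSpec(2, 2)
        vals = np.array([[np.nan, 0.8], [0.8, 0.8]])
        br = binarize(SuitabilityMap(values=vals, grid=grid), 0.5)
        assert not br.presence[0, 0] and br.n_cells == 3

    def test_invalid_threshold_rejected(self):
        grid = GridSpec(2, 2)
        smap = SuitabilityMap(values=np.full(grid.shape, 0.3), grid=grid)
        with pytest.raises(InvalidParameterError):
            binarize(smap, 1.5)


class TestRealized:
    def _setup(self):
        grid = GridSpec(2, 5, cell_size_km=10.0)
        labels = np.array([[1, 1, 1, 2, 2], [1, 1, 1, 2, 2]])
        mosaic = RegionMosaic(labels=labels, grid=grid)
        potential = np.array(
            [[True, True, True, True, True],
             [True, True, True, True, False]]
        )
        return grid, mosaic, _range(potential, grid)

    def _points(self, grid, cells):
        return pd.DataFrame(
            {
                "x": [grid.origin_x + (c + 0.5) * grid.cell_size_km for _r, c in cells],
                "y": [grid.origin_y + (r + 0.5) * grid.cell_size_km for r, _c in cells],
            }
        )

    def test_occurrences_everywhere_keep_potential(self):
        grid, mosaic, pot = self._setup()
        occ = self._points(grid, [(0, 0), (0, 4)])
        realized = realized_from_potential(pot, mosaic, occ)
        np.testing.assert_array_equal(realized.presence, pot.presence)

    def test_single_region_clip(self):
        grid, mosaic, pot = self._setup()
        occ = self._points(grid, [(1, 1)])
        realized = realized_from_potential(pot, mosaic, occ)
        np.testing.assert_array_equal(realized.presence, pot.presence & (mosaic.labels == 1))

    def test_two_region_toy_area_count(self):
        # 9 potential cells: 6 in region 1, 3 in region 2; points only in r1
        grid, mosaic, pot = self._setup()
        occ = self._points(grid, [(0, 0), (1, 2)])
        realized = realized_from_potential(pot, mosaic, occ)
        assert realized.n_cells == 6

    def test_empty_occurrences_rejected(self):
        grid, mosaic, pot = self._setup()
        with pytest.raises(InvalidParameterError):
            realized_from_potential(pot, mosaic, pd.DataFrame({"x": [], "y": []}))

    def test_offgrid_point_warns_and_is_ignored(self):
        grid, mosaic, pot = self._setup()
        occ = pd.DataFrame({"x": [-500.0, grid.origin_x + 5.0],
                            "y": [-500.0, grid.origin_y + 5.0]})
        with pytest.warns(UserWarning, match="outside"):
            realized = realized_from_potential(pot, mosaic, occ)
        assert realized.n_cells == 6


class TestBuildMasks:
    def test_zero_rate_keeps_current(self):
        grid = GridSpec(6, 6, cell_size_km=5.0)
        pres = np.zeros(grid.shape, dtype=bool)
        pres[2, 2] = pres[2, 3] = True
        masks = build_masks(_range(pres, grid), 0.0, 4)
        for m in masks.masks:
            np.testing.assert_array_equal(m, pres)

    def test_single_cell_buffer_matches_brute_force(self):
        # one presence cell, 5-km cells, 3 km/yr: the first decade mask is
        # every cell whose center is within 30 km
        grid = GridSpec(15, 15, cell_size_km=5.0)
        pres = np.zeros(grid.shape, dtype=bool)
        pres[7, 7] = True
        masks = build_masks(_range(pres, grid), 3.0, 1)
        xs, ys = grid.cell_centers()
        dist = np.hypot(xs - xs[7, 7], ys - ys[7, 7])
        np.testing.assert_array_equal(masks.masks[0], dist <= 30.0)

    def test_ten_decades_ten_masks_with_30km_steps(self):
        grid = GridSpec(8, 8, cell_size_km=5.0)
        pres = np.zeros(grid.shape, dtype=bool)
        pres[0, 0] = True
        masks = build_masks(_range(pres, grid), 3.0, 10)
        assert len(masks.masks) == 10
        assert masks.radii_km == [30.0 * d for d in range(1, 11)]

    def test_masks_nested_and_contain_base(self):
        rng = np.random.default_rng(0)
        grid = GridSpec(12, 10, cell_size_km=5.0)
        pres = rng.random(grid.shape) < 0.1
        pres[0, 0] = True
        masks = build_masks(_range(pres, grid), 2.0, 5)
        for d in range(5):
            assert (masks.masks[d] | ~pres).all()  # base inside every mask
            if d:
                assert (masks.masks[d] | ~masks.masks[d - 1]).all()  # nested

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_buffer_equals_all_pairs_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows, cols = rng.integers(5, 31, size=2)
        grid = GridSpec(int(rows), int(cols), cell_size_km=float(rng.integers(2, 8)))
        pres = rng.random(grid.shape) < 0.08
        if not pres.any():
            pres[0, 0] = True
        rate = float(rng.uniform(0.5, 4.0))
        masks = build_masks(_range(pres, grid), rate, 3)
        xs, ys = grid.cell_centers()
        px, py = xs[pres], ys[pres]
        dist = np.min(
            np.hypot(xs[..., None] - px[None, None], ys[..., None] - py[None, None]),
            axis=-1,
        )
        for d, radius in enumerate(masks.radii_km):
            np.testing.assert_array_equal(masks.masks[d], dist <= radius)

    def test_empty_range_warns(self):
        grid = GridSpec(4, 4)
        with pytest.warns(UserWarning, match="empty"):
            masks = build_masks(_range(np.zeros(grid.shape, bool), grid), 3.0, 2)
        assert all(not m.any() for m in masks.masks)


class TestScenarios:
    def _setup(self):
        grid = GridSpec(1, 10, cell_size_km=5.0)
        current = np.zeros(grid.shape, dtype=bool)
        current[0, :3] = True  # realized range: cells 0..2
        future = np.zeros(grid.shape, dtype=bool)
        future[0, 2:] = True  # suitable climate shifted right
        cur = _range(current, grid)
        fut = _range(future, grid)
        masks = build_masks(cur, 3.0, 3)
        return grid, cur, fut, masks

    def test_no_dispersal_never_exceeds_current(self):
        _grid, cur, fut, masks = self._setup()
        out = apply_scenario(fut, "none", cur, masks, decade_index=1)
        assert out.n_cells <= cur.n_cells
        assert (out.presence <= cur.presence).all()

    def test_unbounded_rate_equals_full(self):
        grid, cur, fut, _ = self._setup()
        masks = build_masks(cur, 1e6, 3)
        full = apply_scenario(fut, "full", cur, None)
        rate = apply_scenario(fut, "rate_limited", cur, masks, decade_index=1)
        np.testing.assert_array_equal(full.presence, rate.presence)

    def test_one_dimensional_shift_limited_by_mask_edge(self):
        """Suitable climate 40 km to the right; 30 km of reach admits only
        cells within 30 km of the current range edge (enumeration oracle)."""
        grid, cur, fut, masks = self._setup()
        out = apply_scenario(fut, "rate_limited", cur, masks, decade_index=1)
        # current right edge center x=12.5; 30 km reach covers centers <= 42.5
        # i.e. columns <= 8; intersect with future (cols 2..9)
        expect = np.zeros(grid.shape, dtype=bool)
        expect[0, 2:9] = True
        np.testing.assert_array_equal(out.presence, expect)

    def test_scenario_nesting_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            grid = GridSpec(10, 12, cell_size_km=5.0)
            cur = _range(rng.random(grid.shape) < 0.15, grid)
            if cur.n_cells == 0:
                continue
            fut = _range(rng.random(grid.shape) < 0.4, grid)
            masks = build_masks(cur, 3.0, 4)
            none = apply_scenario(fut, "none", cur, masks, decade_index=2)
            rate = apply_scenario(fut, "rate_limited", cur, masks, decade_index=2)
            full = apply_scenario(fut, "full", cur, masks, decade_index=2)
            assert (none.presence <= rate.presence).all()
            assert (rate.presence <= full.presence).all()

    def test_rate_limited_without_masks_rejected(self):
        _grid, cur, fut, _ = self._setup()
        with pytest.raises(MissingDataError):
            apply_scenario(fut, "rate_limited", cur, None, decade_index=1)

    def test_region_level_no_dispersal(self):
        grid, cur, fut, masks = self._setup()
        region_mask = np.zeros(grid.shape, dtype=bool)
        region_mask[0, :5] = True
        out = apply_scenario(fut, "none", cur, masks, decade_index=1,
                             none_level="region", occupied_region_mask=region_mask)
        np.testing.assert_array_equal(out.presence, fut.presence & region_mask)


class TestRealistic:
    def test_selects_matching_category(self):
        grid = GridSpec(2, 2)
        outs = {
            "full": _range(np.ones(grid.shape, bool), grid),
            "rate_limited": _range(np.eye(2, dtype=bool), grid),
            "none": _range(np.zeros(grid.shape, bool), grid),
        }
        for category in ("full", "none"):
            meta = SpeciesMeta("sp", dispersal_category=category)
            chosen = realistic_scenario(meta, outs)
            np.testing.assert_array_equal(chosen.presence, outs[category].presence)
            assert chosen.scenario == "realistic"
        meta = SpeciesMeta("sp", dispersal_category="rate_limited",
                           dispersal_rate_km_per_year=3.0)
        chosen = realistic_scenario(meta, outs)
        np.testing.assert_array_equal(chosen.presence, outs["rate_limited"].presence)

    def test_unknown_category_rejected(self):
        meta = SpeciesMeta("sp", dispersal_category="full")
        with pytest.raises(SchemaError):
            realistic_scenario(meta, {"none": None})
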