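"""Normalized cell coordinates, binning, density maps, representative cells."""

import numpy as np
import pandas as pd
import pytest

from bactorg import cellmap, cellseg, synthgen
from bactorg.cellmap import BinSpec, bin_localizations, density_map


@pytest.fixture(scope="module")
def rod_setup(rod_mask, rod_morphology):
    return rod_mask, rod_morphology


def _uniform_points_in_mask(mask, n, seed):
    ys, xs = np.nonzero(mask)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ys), size=n)
    # jitter within the pixel to avoid lattice artifacts
    return np.column_stack(
        [xs[idx] + rng.uniform(-0.5, 0.5, n), ys[idx] + rng.uniform(-0.5, 0.5, n)]
    )


class TestCellCoords:
    def test_midline_point_is_cylindrical_center(self, rod_setup):
        mask, morph = rod_setup
        arc = morph.midline_arclength_px()
        i = np.searchsorted(arc, arc[-1] / 2)
        x, y = morph.midline[i]
        c = cellmap.to_cell_coords(x, y, morph, 60.0)
        assert c.region == "cylindrical"
        assert c.r_rel == pytest.approx(0.0, abs=0.05)
        assert c.l_rel == pytest.approx(0.5, abs=0.05)

    def test_pole_tip_polar_phi_zero(self, rod_setup):
        mask, morph = rod_setup
        end = morph.midline[-1]
        prev = morph.midline[-5]
        v = (end - prev) / np.hypot(*(end - prev))
        tip = end + 2.0 * v
        c = cellmap.to_cell_coords(tip[0], tip[1], morph, 60.0)
        assert c.region == "polar"
        assert c.l_rel in (0.0, 1.0)
        assert c.phi == pytest.approx(0.0, abs=0.05)

    def test_mirror_symmetry(self, rod_setup):
        mask, morph = rod_setup
        # rod midline is horizontal near y = 13; mirror across it
        a = cellmap.to_cell_coords(30.0, 9.0, morph, 60.0)
        b = cellmap.to_cell_coords(30.0, 17.0, morph, 60.0)
        assert a.r_rel == pytest.approx(b.r_rel, abs=0.02)
        assert a.l_rel == pytest.approx(b.l_rel, abs=0.02)
        assert a.side != b.side

    def test_point_outside_mask_rejected(self, rod_setup):
        mask, morph = rod_setup
        with pytest.raises(ValueError):
            cellmap.to_cell_coords(0.0, 0.0, morph, 60.0, cell_mask=mask)

    def test_cylindrical_round_trip(self, rod_setup):
        mask, morph = rod_setup
        pts = _uniform_points_in_mask(mask, 200, seed=1)
        coords = cellmap.cell_coords_batch(pts, morph, 60.0)
        for (x, y), c in zip(pts, coords):
            if c.region != "cylindrical" or c.l_rel in (0.0, 1.0):
                continue
            rx, ry = cellmap.from_cell_coords(c, morph, 60.0)
            assert np.hypot(rx - x, ry - y) <= 0.5


class TestBinning:
    def test_single_localization_single_bin(self, rod_setup):
        mask, morph = rod_setup
        locs = pd.DataFrame({"cell_id": [1], "x": [30.0], "y": [13.0]})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        assert grid.counts.sum() == 1
        assert (grid.counts > 0).sum() == 1

    def test_bin_areas_tile_cell(self, rod_setup):
        mask, morph = rod_setup
        grid = bin_localizations(pd.DataFrame({"cell_id": [], "x": [], "y": []}), {1: morph}, {1: mask})
        px_area = 0.06**2
        assert grid.areas_um2.sum() == pytest.approx(mask.sum() * px_area, rel=1e-9)
        assert grid.overflow == 0

    def test_uniform_points_multinomial_bounds(self, rod_setup):
        mask, morph = rod_setup
        n = 10_000
        pts = _uniform_points_in_mask(mask, n, seed=2)
        # keep points whose nearest pixel is in the mask
        keep = mask[
            np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[0] - 1),
            np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[1] - 1),
        ]
        pts = pts[keep]
        locs = pd.DataFrame({"cell_id": 1, "x": pts[:, 0], "y": pts[:, 1]})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        areas = grid.areas_um2[0]
        counts = grid.counts[0]
        total_area = areas.sum()
        total = counts.sum()
        for a, c in zip(areas, counts):
            if a == 0:
                continue
            p = a / total_area
            sd = np.sqrt(total * p * (1 - p))
            assert abs(c - total * p) <= 4 * sd + 1

    def test_all_mask_pixels_have_a_bin(self, rod_setup):
        mask, morph = rod_setup
        ys, xs = np.nonzero(mask)
        locs = pd.DataFrame({"cell_id": 1, "x": xs.astype(float), "y": ys.astype(float)})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        assert grid.counts.sum() == mask.sum()
        assert grid.overflow == 0


class TestDensityMap:
    def test_conservation(self, rod_setup):
        mask, morph = rod_setup
        pts = _uniform_points_in_mask(mask, 500, seed=3)
        locs = pd.DataFrame({"cell_id": 1, "x": pts[:, 0], "y": pts[:, 1]})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        for sym in (False, True):
            dm = density_map(grid, symmetrize=sym)
            assert dm.conservation() == pytest.approx(dm.n_cells, rel=1e-6)

    def test_uniform_input_flat_density(self, rod_setup):
        mask, morph = rod_setup
        pts = _uniform_points_in_mask(mask, 20_000, seed=4)
        locs = pd.DataFrame({"cell_id": 1, "x": pts[:, 0], "y": pts[:, 1]})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        dm = density_map(grid, symmetrize=True)
        t = dm.bin_table
        cell_area = mask.sum() * 0.06**2
        good = t.summed_area_um2 > 0.02  # skip slivers with huge relative noise
        assert t.density_per_um2[good].mean() == pytest.approx(1.0 / cell_area, rel=0.05)
        assert t.density_per_um2[good].std() / t.density_per_um2[good].mean() < 0.25

    def test_mirrored_input_equals_symmetrized(self, rod_setup):
        mask, morph = rod_setup
        pts = _uniform_points_in_mask(mask, 300, seed=5)
        locs = pd.DataFrame({"cell_id": 1, "x": pts[:, 0], "y": pts[:, 1]})
        # mirror across the horizontal midline (rod is axis-aligned, y = 13)
        mirrored = locs.assign(y=26.0 - locs.y)
        g1 = bin_localizations(locs, {1: morph}, {1: mask})
        g2 = bin_localizations(mirrored, {1: morph}, {1: mask})
        d1 = density_map(g1, symmetrize=True)
        d2 = density_map(g2, symmetrize=True)
        np.testing.assert_allclose(
            d1.bin_table.density_per_um2, d2.bin_table.density_per_um2, atol=1e-9
        )

    def test_midcell_axial_concentration(self, rod_setup):
        mask, morph = rod_setup
        rng = np.random.default_rng(6)
        xs = rng.uniform(35, 41, 200)
        ys = rng.uniform(12.5, 13.5, 200)
        locs = pd.DataFrame({"cell_id": 1, "x": xs, "y": ys})
        grid = bin_localizations(locs, {1: morph}, {1: mask})
        dm = density_map(grid, symmetrize=True)
        t = dm.bin_table
        inner = t[(t.region == "cylindrical") & (t.ring == 0)].summed_count.sum()
        assert inner == 200  # all mass in the lowest-r ring

    def test_zero_counts_flagged(self, rod_setup):
        mask, morph = rod_setup
        grid = bin_localizations(pd.DataFrame({"cell_id": [], "x": [], "y": []}), {1: morph}, {1: mask})
        dm = density_map(grid)
        assert dm.flagged
        assert np.all(dm.bin_table.density_per_um2 == 0)


class TestEquivariance:
    def test_rot90_leaves_symmetrized_map_unchanged(self, rod_setup):
        mask, morph = rod_setup
        pts = _uniform_points_in_mask(mask, 400, seed=7)
        locs = pd.DataFrame({"cell_id": 1, "x": pts[:, 0], "y": pts[:, 1]})
        g1 = bin_localizations(locs, {1: morph}, {1: mask})
        d1 = density_map(g1, symmetrize=True)

        rot_mask = np.rot90(mask)
        labels = np.zeros_like(rot_mask, dtype=np.int32)
        labels[rot_mask] = 1
        (rot_morph,) = cellseg.cell_morphology(labels, 60.0)
        w = mask.shape[1]
        # (x, y) -> (y, w-1-x) under np.rot90 of the image grid
        rot_locs = pd.DataFrame({"cell_id": 1, "x": locs.y, "y": w - 1 - locs.x})
        g2 = bin_localizations(rot_locs, {1: rot_morph}, {1: rot_mask})
        d2 = density_map(g2, symmetrize=True)
        v1 = np.sort(d1.bin_table.density_per_um2.to_numpy())
        v2 = np.sort(d2.bin_table.density_per_um2.to_numpy())
        assert np.allclose(v1, v2, rtol=0.05, atol=0.5)


class TestRepresentativeCell:
    def test_identical_masks_reproduce_mask(self, rod_mask):
        rep, morph = cellmap.representative_cell([rod_mask] * 5)
        assert rep.sum() == pytest.approx(rod_mask.sum(), rel=0.02)
        assert morph.length_um == pytest.approx(4.0, rel=0.07)

    def test_two_rod_lengths_intermediate(self):
        a = synthgen.make_cell_mask(2.5, 1.0)
        b = synthgen.make_cell_mask(4.0, 1.0)
        rep, morph = cellmap.representative_cell([a, b])
        assert 2.5 * 0.9 <= morph.length_um <= 4.0 * 1.1

    def test_representative_connected(self, rod_mask):
        from scipy import ndimage as ndi

        rep, _ = cellmap.representative_cell([rod_mask, np.rot90(rod_mask)])
        _, n = ndi.label(rep)
        assert n == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cellmap.representative_cell([])
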