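"""Grid geometry, rasterization, margin expansion and mask I/O."""

import numpy as np
import pytest

from contourqa.volumes import (
    ContourSet,
    CoordinateMismatchError,
    EmptyStructureError,
    InvalidContourError,
    StructureMask,
    StructureSet,
    VoxelGrid,
    expand_margin,
    rasterize_contours,
    read_mask_text,
    read_rtstruct,
    standardize_name,
    surface_points,
    volume_cc,
    write_mask_text,
    write_rtstruct,
)

from conftest import cube_mask, mask_from_indices


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def point_in_polygon(px, py, poly):
    """Independent even-odd ray-casting test (horizontal ray to +x)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def brute_force_expand(mask, radius_fn):
    """Set every voxel within the direction-dependent reach of any set
    voxel, by exhaustive pairwise check."""
    grid = mask.grid
    set_idx = np.argwhere(mask.occupancy)
    out = np.zeros(grid.dims, dtype=bool)
    sp = np.asarray(grid.spacing)
    for idx in np.ndindex(*grid.dims):
        for s in set_idx:
            d = (np.asarray(idx) - s) * sp
            if radius_fn(d) <= 1.0 + 1e-12:
                out[idx] = True
                break
    return out


def iso_radius_fn(r):
    return lambda d: (np.linalg.norm(d) / r) if r > 0 else (0.0 if not d.any() else np.inf)


# ---------------------------------------------------------------------------
# VoxelGrid
# ---------------------------------------------------------------------------

class TestVoxelGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (1, 0, 1), (5, 5, 5))
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (1, 1, 1), (5, 0, 5))
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (1, 1, 1), (5, 5, 5), posterior="+z")

    def test_voxel_volume(self):
        g = VoxelGrid((0, 0, 0), (5, 5, 5), (4, 4, 4))
        assert g.voxel_volume_cc == pytest.approx(0.125)

    def test_direction_mapping_lps(self, unit_grid):
        assert unit_grid.direction_axis("posterior") == (1, 1)
        assert unit_grid.direction_axis("anterior") == (1, -1)
        assert unit_grid.direction_axis("left") == (0, 1)
        assert unit_grid.direction_axis("superior") == (2, 1)

    def test_posterior_flag_moves_axis(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (5, 5, 5), posterior="-x")
        assert g.direction_axis("posterior") == (0, -1)
        assert g.direction_axis("left") == (1, 1)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

class TestRasterize:
    def test_square_encloses_four_centers(self, unit_grid):
        # 2x2 mm square centered at (4.5, 4.5) on slice z=3 encloses the
        # centers (4,4), (4,5), (5,4), (5,5)
        poly = np.array([[3.5, 3.5], [5.5, 3.5], [5.5, 5.5], [3.5, 5.5]])
        cs = ContourSet("sq", [(3.0, [poly])])
        mask = rasterize_contours(cs, unit_grid)
        assert mask.voxel_count == 4
        expected = {(4, 4, 3), (4, 5, 3), (5, 4, 3), (5, 5, 3)}
        assert set(map(tuple, np.argwhere(mask.occupancy))) == expected

    def test_empty_contour_set(self, unit_grid):
        mask = rasterize_contours(ContourSet("none", []), unit_grid)
        assert mask.is_empty

    def test_annulus_even_odd(self, unit_grid):
        outer = np.array([[0.5, 0.5], [8.5, 0.5], [8.5, 8.5], [0.5, 8.5]])
        inner = np.array([[2.5, 2.5], [6.5, 2.5], [6.5, 6.5], [2.5, 6.5]])
        cs = ContourSet("ann", [(5.0, [outer, inner])])
        mask = rasterize_contours(cs, unit_grid)
        assert mask.occupancy[1, 1, 5]  # inside outer only
        assert not mask.occupancy[4, 4, 5]  # inside both -> hole
        assert not mask.occupancy[9, 9, 5]  # outside

    def test_matches_ray_casting_oracle(self, unit_grid):
        rng = np.random.default_rng(0)
        pts = rng.uniform(1, 8, size=(7, 2))
        hull_order = np.argsort(np.arctan2(*(pts - pts.mean(0)).T[::-1]))
        poly = pts[hull_order]
        cs = ContourSet("rand", [(2.0, [poly])])
        mask = rasterize_contours(cs, unit_grid)
        for i in range(10):
            for j in range(10):
                assert mask.occupancy[i, j, 2] == point_in_polygon(i, j, poly), (i, j)

    def test_z_outside_grid_rejected(self, unit_grid):
        poly = np.array([[1, 1], [3, 1], [2, 3]])
        with pytest.raises(CoordinateMismatchError):
            rasterize_contours(ContourSet("bad", [(15.0, [poly])]), unit_grid)
        with pytest.raises(CoordinateMismatchError):
            rasterize_contours(ContourSet("bad", [(-3.0, [poly])]), unit_grid)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(InvalidContourError):
            ContourSet("line", [(0.0, [np.array([[0, 0], [1, 1]])])])

    def test_prism_volume_converges_with_spacing(self):
        # square prism 20x20 mm x 10 slices; analytic volume known
        poly = np.array([[10.0, 10.0], [30.0, 10.0], [30.0, 30.0], [10.0, 30.0]])
        analytic_cc = 20 * 20 * 10 / 1000.0
        errs = []
        for sp in (2.0, 0.5):
            nz = int(10 / sp)
            g = VoxelGrid((0, 0, 0), (sp, sp, sp), (int(40 / sp), int(40 / sp), nz))
            slices = [(g.z_positions[k], [poly]) for k in range(nz)]
            m = rasterize_contours(ContourSet("p", slices), g)
            errs.append(abs(m.volume_cc - analytic_cc) / analytic_cc)
        assert errs[1] < errs[0]
        assert errs[1] < 0.05


# ---------------------------------------------------------------------------
# Margin expansion
# ---------------------------------------------------------------------------

class TestExpandMargin:
    def test_isotropic_matches_brute_force(self, unit_grid):
        m = mask_from_indices(unit_grid, [(5, 5, 5)])
        out = expand_margin(m, 3.0)
        expect = brute_force_expand(m, iso_radius_fn(3.0))
        assert np.array_equal(out.occupancy, expect)

    def test_single_voxel_5mm_reach(self, unit_grid):
        m = mask_from_indices(unit_grid, [(5, 5, 5)])
        out = expand_margin(m, 5.0)
        centers = np.argwhere(out.occupancy) - [5, 5, 5]
        dist = np.linalg.norm(centers, axis=1)
        assert dist.max() <= 5.0 + 1e-9
        # every voxel within 5 mm, clipped to indices 0..9 on each axis
        n_inside_sphere = int(sum(
            np.linalg.norm([i, j, k]) <= 5
            for i in range(-5, 5) for j in range(-5, 5) for k in range(-5, 5)
        ))
        assert out.voxel_count == n_inside_sphere

    def test_zero_margin_is_identity(self, unit_grid):
        m = cube_mask(unit_grid, (2, 2, 2), (5, 5, 5))
        out = expand_margin(m, 0.0)
        assert np.array_equal(out.occupancy, m.occupancy)

    def test_posterior_margin_shorter(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 1), (15, 15, 15))
        m = mask_from_indices(g, [(7, 7, 7)])
        out = expand_margin(m, {"left": 5, "right": 5, "anterior": 5,
                                "posterior": 3, "superior": 5, "inferior": 5})
        ys = np.argwhere(out.occupancy)[:, 1]
        assert ys.max() == 7 + 3   # posterior (+y) reach 3 mm
        assert ys.min() == 7 - 5   # anterior reach 5 mm
        # matches the brute-force anisotropic oracle
        def radius_fn(d):
            r = np.array([5.0, 3.0 if d[1] > 0 else 5.0, 5.0])
            return np.sqrt(((d / r) ** 2).sum())
        expect = brute_force_expand(m, radius_fn)
        assert np.array_equal(out.occupancy, expect)

    def test_monotone_in_margin(self, unit_grid):
        m = cube_mask(unit_grid, (4, 4, 4), (6, 6, 6))
        small = expand_margin(m, 2.0)
        large = expand_margin(m, 4.0)
        assert np.all(m.occupancy <= small.occupancy)
        assert np.all(small.occupancy <= large.occupancy)

    def test_anisotropic_spacing(self):
        g = VoxelGrid((0, 0, 0), (1, 1, 5), (11, 11, 7))
        m = mask_from_indices(g, [(5, 5, 3)])
        out = expand_margin(m, 5.0)
        ks = np.argwhere(out.occupancy)[:, 2]
        assert ks.max() == 4 and ks.min() == 2  # one 5 mm slice each way


# ---------------------------------------------------------------------------
# Volume and surface
# ---------------------------------------------------------------------------

class TestVolumeSurface:
    def test_volume_1000_unit_voxels_is_1cc(self, unit_grid):
        m = cube_mask(unit_grid, (0, 0, 0), (10, 10, 10))
        assert volume_cc(m) == pytest.approx(1.0)

    def test_volume_coarse_grid(self):
        g = VoxelGrid((0, 0, 0), (5, 5, 5), (2, 2, 2))
        m = cube_mask(g, (0, 0, 0), (2, 2, 2))
        assert volume_cc(m) == pytest.approx(1.0)

    def test_empty_volume_zero(self, unit_grid):
        m = mask_from_indices(unit_grid, [])
        assert volume_cc(m) == 0.0

    def test_single_voxel_is_all_surface(self, unit_grid):
        m = mask_from_indices(unit_grid, [(3, 4, 5)])
        pts = surface_points(m)
        assert pts.shape == (1, 3)
        assert np.allclose(pts[0], [3, 4, 5])

    def test_cube_surface_excludes_center(self, unit_grid):
        m = cube_mask(unit_grid, (3, 3, 3), (6, 6, 6))
        pts = surface_points(m)
        assert len(pts) == 26
        assert not any(np.allclose(p, [4, 4, 4]) for p in pts)

    def test_slab_is_all_surface(self, unit_grid):
        m = cube_mask(unit_grid, (2, 2, 5), (8, 8, 6))
        assert len(surface_points(m)) == m.voxel_count

    def test_surface_subset_of_mask(self, unit_grid):
        rng = np.random.default_rng(1)
        occ = rng.random(unit_grid.dims) < 0.4
        m = StructureMask("r", unit_grid, occ)
        pts = surface_points(m)
        for p in pts:
            assert m.occupancy[tuple(p.astype(int))]

    def test_empty_mask_raises(self, unit_grid):
        with pytest.raises(EmptyStructureError):
            surface_points(mask_from_indices(unit_grid, []))


# ---------------------------------------------------------------------------
# Names, structure sets, I/O
# ---------------------------------------------------------------------------

class TestNamesAndIO:
    def test_standardize_known_aliases(self):
        assert standardize_name("Parotid_C") == "Contralateral Parotid"
        assert standardize_name("BrachialPlexus_O") == "Ipsilateral Brachial Plexus"
        assert standardize_name("Femur Left") == "Left Femur"
        assert standardize_name("SpinalCord") == "Spinal Cord"

    def test_unknown_name_passes_through(self):
        assert standardize_name(" Custom ROI ") == "Custom ROI"

    def test_structure_set_standardizes_keys(self, unit_grid):
        m = cube_mask(unit_grid, (0, 0, 0), (2, 2, 2), name="Femur_L")
        s = StructureSet("manual", {"Femur_L": m})
        assert "Left Femur" in s.names()
        assert s["Femur Left"] is m

    def test_mask_text_roundtrip(self, tmp_path, unit_grid):
        rng = np.random.default_rng(2)
        occ = rng.random(unit_grid.dims) < 0.5
        m = StructureMask("Anal Canal", unit_grid, occ)
        f = tmp_path / "m.mask"
        write_mask_text(m, f)
        back = read_mask_text(f)
        assert back.name == "Anal Canal"
        assert back.grid == unit_grid
        assert np.array_equal(back.occupancy, m.occupancy)

    def test_rtstruct_roundtrip(self, tmp_path):
        poly = np.array([[1.0, 1.0], [4.0, 1.0], [4.0, 4.0], [1.0, 4.0]])
        cs = ContourSet("Bladder", [(0.0, [poly]), (1.0, [poly + 0.5])])
        f = tmp_path / "rs.dcm"
        write_rtstruct([cs], f)
        back = read_rtstruct(f)
        assert len(back) == 1
        assert back[0].name == "Bladder"
        assert len(back[0].slices) == 2
        np.testing.assert_allclose(back[0].slices[0][1][0], poly)
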