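"""Geometric agreement metrics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest

from oareval import (
    BinaryMask,
    MetricConfig,
    StructureSet,
    VoxelGrid,
    added_path_length,
    compare_masks,
    compare_structure_sets,
    contour_dice,
    delta_centroid,
    delta_volume,
    extract_boundary,
    hausdorff95,
    results_to_dataframe,
    surface_dice,
    translate_mask_voxels,
    volumetric_dice,
    voxel_confusion,
)
from oareval.errors import InvalidParameterError, UndefinedMetricError
from oareval.metrics import _slice_boundary_indices

from conftest import cube_mask, sphere_mask
from oracles import (
    brute_apl,
    brute_cdc,
    brute_hd95,
    brute_surface_dice,
    lens_volume,
    random_blob,
)


def _boundary_points(mask):
    return extract_boundary(mask).voxel_centers


def _ref_slice_points(mask):
    grid = mask.grid
    pts = []
    for k in range(grid.shape[2]):
        idx2 = _slice_boundary_indices(mask.occupancy[:, :, k])
        for i, j in idx2:
            pts.append(grid.index_to_world(np.array([i, j, k]))[0])
    return np.asarray(pts) if pts else np.empty((0, 3))


def random_pair(rng, shape=(16, 16, 12), spacing=(1.0, 1.0, 1.5)):
    grid = VoxelGrid((0, 0, 0), spacing, shape)
    while True:
        a = random_blob(rng, shape, threshold=0.6)
        b = random_blob(rng, shape, threshold=0.6)
        if a.any() and b.any():
            return BinaryMask(grid, a), BinaryMask(grid, b)


class TestVolumetricDice:
    def test_identity_and_disjoint(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        b = cube_mask(iso_grid, (12, 12, 12), (5, 5, 5))
        assert volumetric_dice(a, a) == 1.0
        assert volumetric_dice(a, b) == 0.0

    def test_both_empty_undefined(self, iso_grid):
        with pytest.raises(UndefinedMetricError):
            volumetric_dice(BinaryMask.empty(iso_grid), BinaryMask.empty(iso_grid))

    def test_sphere_pair_matches_lens_closed_form(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (46, 40, 40))
        r, d = 10.0, 5.0
        a = sphere_mask(grid, (17.5, 19.5, 19.5), r)
        b = sphere_mask(grid, (22.5, 19.5, 19.5), r)
        expected = 2 * lens_volume(r, d) / (2 * 4 / 3 * np.pi * r ** 3)
        assert volumetric_dice(a, b) == pytest.approx(expected, abs=0.01)


class TestSurfaceDice:
    def test_identity_and_far_separation(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        b = cube_mask(iso_grid, (15, 15, 15), (5, 5, 5))
        assert surface_dice(a, a, 1.0) == 1.0
        assert surface_dice(a, b, 1.0) == 0.0

    def test_invalid_tau_rejected(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        with pytest.raises(InvalidParameterError):
            surface_dice(a, a, 0.0)

    def test_translated_cube_matches_brute_force_exactly(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (16, 16, 16))
        a = cube_mask(grid, (2, 2, 2), (10, 10, 10))
        b = translate_mask_voxels(a, (2, 0, 0))
        got = surface_dice(a, b, 1.0)
        expected = brute_surface_dice(extract_boundary(a), extract_boundary(b), 1.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_tau(self, iso_grid):
        rng = np.random.default_rng(5)
        a, b = random_pair(rng)
        values = [surface_dice(a, b, tau) for tau in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))


class TestHausdorff95:
    def test_identity_zero(self, iso_grid):
        a = cube_mask(iso_grid, (3, 3, 3), (6, 6, 6))
        assert hausdorff95(a, a) == 0.0

    def test_single_voxel_pair_distance(self, iso_grid):
        a = cube_mask(iso_grid, (5, 5, 5), (1, 1, 1))
        b = cube_mask(iso_grid, (8, 5, 5), (1, 1, 1))
        assert hausdorff95(a, b) == pytest.approx(3.0)

    def test_random_blobs_match_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a, b = random_pair(rng)
            got = hausdorff95(a, b)
            expected = brute_hd95(_boundary_points(a), _boundary_points(b))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_hd95_bounded_by_exact_hausdorff(self):
        rng = np.random.default_rng(33)
        from scipy.spatial.distance import cdist
        for _ in range(5):
            a, b = random_pair(rng)
            pa, pb = _boundary_points(a), _boundary_points(b)
            d = cdist(pa, pb)
            exact = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff95(a, b) <= exact + 1e-9


class TestAddedPathLength:
    def test_identity_zero(self, iso_grid):
        a = cube_mask(iso_grid, (3, 3, 3), (6, 6, 6))
        assert added_path_length(a, a, 1.0) == 0.0

    def test_empty_candidate_full_reference_path(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (14, 14, 3))
        ref = cube_mask(grid, (2, 2, 1), (10, 10, 1))  # one-slice 10x10 square
        apl = added_path_length(BinaryMask.empty(grid), ref, 1.0)
        assert apl == pytest.approx(36.0)

    def test_shifted_ring_matches_brute_force(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (16, 16, 3))
        ref = cube_mask(grid, (2, 2, 1), (10, 10, 1))
        cand = translate_mask_voxels(ref, (2, 0, 0))
        got = added_path_length(cand, ref, 1.0)
        expected = brute_apl(_ref_slice_points(ref), _boundary_points(cand), 1.0, 1.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(9)
        a, b = random_pair(rng)
        values = [added_path_length(a, b, tol) for tol in (0.0, 1.0, 2.0, 5.0)]
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))

    def test_not_symmetric_reference_anchored(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (20, 20, 6))
        small = cube_mask(grid, (5, 5, 2), (4, 4, 2))
        large = cube_mask(grid, (3, 3, 1), (14, 14, 4))
        assert added_path_length(small, large, 1.0) != pytest.approx(
            added_path_length(large, small, 1.0)
        )

    def test_empty_reference_undefined(self, iso_grid):
        with pytest.raises(UndefinedMetricError):
            added_path_length(
                cube_mask(iso_grid, (1, 1, 1), (3, 3, 3)),
                BinaryMask.empty(iso_grid), 1.0,
            )


class TestContourDice:
    def test_identity_and_far(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        b = cube_mask(iso_grid, (15, 15, 15), (5, 5, 5))
        assert contour_dice(a, a, 1.0) == 1.0
        assert contour_dice(a, b, 1.0) == 0.0

    def test_dilated_cube_matches_brute_force(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (16, 16, 16))
        a = cube_mask(grid, (3, 3, 3), (8, 8, 8))
        b = cube_mask(grid, (2, 2, 2), (10, 10, 10))  # 1-voxel dilation
        got = contour_dice(a, b, 1.0)
        expected = brute_cdc(_boundary_points(a), _boundary_points(b), 1.0)
        assert got == pytest.approx(expected, abs=1e-12)


class TestVoxelConfusion:
    def test_identity_perfect(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        c = voxel_confusion(a, a)
        assert (c.precision, c.sensitivity, c.specificity) == (1.0, 1.0, 1.0)

    def test_superset_candidate(self, iso_grid):
        ref = cube_mask(iso_grid, (3, 3, 3), (5, 5, 5))
        cand = cube_mask(iso_grid, (2, 2, 2), (7, 7, 7))
        c = voxel_confusion(cand, ref)
        assert c.sensitivity == 1.0
        assert c.precision < 1.0

    def test_hand_counted_toy_masks(self, iso_grid):
        cand = cube_mask(iso_grid, (0, 0, 0), (4, 4, 4))   # 64 voxels
        ref = cube_mask(iso_grid, (2, 0, 0), (4, 4, 4))    # overlap 2x4x4=32
        c = voxel_confusion(cand, ref)
        total = 24 ** 3
        assert c.precision == pytest.approx(32 / 64)
        assert c.sensitivity == pytest.approx(32 / 64)
        assert c.specificity == pytest.approx((total - 96) / (total - 64))

    def test_degenerate_rates_are_nan_not_zero(self, iso_grid):
        empty = BinaryMask.empty(iso_grid)
        c = voxel_confusion(empty, empty)
        assert math.isnan(c.precision)
        assert math.isnan(c.sensitivity)
        assert c.specificity == 1.0


class TestDeltas:
    def test_delta_volume_signed(self, iso_grid):
        ref = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        grid2 = VoxelGrid((0, 0, 0), (1, 1, 2), (20, 20, 20))
        a = cube_mask(grid2, (0, 0, 0), (10, 10, 10))  # 1000 voxels
        b = cube_mask(grid2, (0, 0, 0), (10, 10, 15))  # +500 voxels of 2 mm3
        assert delta_volume(b, a) == pytest.approx(1.0)
        sub = cube_mask(iso_grid, (2, 2, 2), (4, 4, 4))
        assert delta_volume(sub, ref) < 0
        assert delta_volume(ref, ref) == 0.0

    def test_delta_centroid_pythagoras(self, iso_grid):
        a = cube_mask(iso_grid, (2, 2, 2), (6, 6, 6))
        b = translate_mask_voxels(a, (3, 4, 0))
        assert delta_centroid(b, a) == pytest.approx(5.0)
        assert delta_centroid(a, a) == 0.0

    def test_symmetric_dilation_keeps_centroid(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (21, 21, 21))
        small = sphere_mask(grid, (10, 10, 10), 4.0)
        big = sphere_mask(grid, (10, 10, 10), 7.0)
        assert delta_centroid(big, small) == pytest.approx(0.0, abs=1e-9)


class TestSymmetryAndEquivariance:
    def test_symmetric_metrics(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a, b = random_pair(rng)
            assert volumetric_dice(a, b) == pytest.approx(volumetric_dice(b, a))
            assert surface_dice(a, b, 1.5) == pytest.approx(
                surface_dice(b, a, 1.5), abs=1e-12
            )
            assert hausdorff95(a, b) == pytest.approx(hausdorff95(b, a), abs=1e-12)
            assert contour_dice(a, b, 1.0) == pytest.approx(
                contour_dice(b, a, 1.0), abs=1e-12
            )

    def test_joint_translation_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(19)
        grid = VoxelGrid((0, 0, 0), (1, 1, 1.5), (20, 20, 16))

        def interior_blob():
            occ = random_blob(rng, grid.shape, threshold=0.5)
            # keep clear of the border so the joint shift clips nothing
            border = np.zeros(grid.shape, dtype=bool)
            border[3:-3, 3:-3, 3:-3] = True
            occ &= border
            assert occ.any()
            return BinaryMask(grid, occ)

        a = interior_blob()
        b = interior_blob()
        shift = (2, 1, 1)
        a2 = translate_mask_voxels(a, shift)
        b2 = translate_mask_voxels(b, shift)
        assert volumetric_dice(a, b) == pytest.approx(volumetric_dice(a2, b2))
        assert hausdorff95(a, b) == pytest.approx(hausdorff95(a2, b2), abs=1e-9)
        assert surface_dice(a, b, 2.0) == pytest.approx(
            surface_dice(a2, b2, 2.0), abs=1e-9
        )
        assert added_path_length(a, b, 1.0) == pytest.approx(
            added_path_length(a2, b2, 1.0), abs=1e-9
        )


class TestCompareStructureSets:
    def _sets(self, iso_grid):
        gs = StructureSet("c1", "GS", {
            "Parotid_L": cube_mask(iso_grid, (2, 2, 2), (6, 6, 6)),
            "Parotid_R": cube_mask(iso_grid, (12, 12, 12), (6, 6, 6)),
            "Brainstem": sphere_mask(iso_grid, (12, 6, 12), 4.0),
            "Lens_L": cube_mask(iso_grid, (18, 2, 2), (2, 2, 2)),
            "A_Carotid_L": cube_mask(iso_grid, (2, 18, 2), (2, 2, 8)),
        })
        cand = StructureSet("c1", "DL", {
            "Parotid_L": translate_mask_voxels(gs.get("Parotid_L"), (1, 0, 0)),
            "Parotid_R": gs.get("Parotid_R"),
            "Brainstem": gs.get("Brainstem"),
            "Lens_L": None,                       # absent
            "A_Carotid_L": BinaryMask.empty(iso_grid),  # delivered empty
        })
        return gs, cand

    def test_self_comparison_is_perfect(self, iso_grid):
        gs, _ = self._sets(iso_grid)
        results = compare_structure_sets(gs, gs)
        df = results_to_dataframe(results)
        assert (df.loc[df.metric == "VDSC", "value"] == 1.0).all()
        assert (df.loc[df.metric == "HD95", "value"] == 0.0).all()
        assert (df.loc[df.metric == "APL", "value"] == 0.0).all()
        assert (df.loc[df.metric == "DeltaCentroid", "value"] == 0.0).all()

    def test_absent_and_empty_structures_skipped(self, iso_grid):
        gs, cand = self._sets(iso_grid)
        df = results_to_dataframe(compare_structure_sets(cand, gs))
        assert set(df.structure) == {"Parotid_L", "Parotid_R", "Brainstem"}

    def test_battery_matches_single_op_calls(self, iso_grid):
        gs, cand = self._sets(iso_grid)
        df = results_to_dataframe(compare_structure_sets(cand, gs))
        sub = df[(df.structure == "Parotid_L")]
        a = cand.get("Parotid_L")
        r = gs.get("Parotid_L")
        assert sub.loc[sub.metric == "VDSC", "value"].iloc[0] == pytest.approx(
            volumetric_dice(a, r)
        )
        sdsc_15 = sub[(sub.metric == "SDSC") & (sub.parameter_mm == 1.5)]
        assert sdsc_15["value"].iloc[0] == pytest.approx(surface_dice(a, r, 1.5))
        apl_2 = sub[(sub.metric == "APL") & (sub.parameter_mm == 2.0)]
        assert apl_2["value"].iloc[0] == pytest.approx(added_path_length(a, r, 2.0))

    def test_default_tolerance_battery(self, iso_grid):
        gs, _ = self._sets(iso_grid)
        df = results_to_dataframe(compare_structure_sets(gs, gs))
        one = df[df.structure == "Parotid_L"]
        assert sorted(one.loc[one.metric == "SDSC", "parameter_mm"]) == [1, 1.5, 2, 3]
        assert sorted(one.loc[one.metric == "APL", "parameter_mm"]) == [1, 2, 3, 5]
        assert list(one.loc[one.metric == "CDC", "parameter_mm"]) == [1]

    def test_grid_mismatch_resampled_with_warning(self, iso_grid, caplog):
        gs, _ = self._sets(iso_grid)
        fine = VoxelGrid((0, 0, 0), (0.5, 0.5, 0.5), (48, 48, 48))
        cand_structs = {
            name: (None if m is None else __import__("oareval").resample_nearest(m, fine))
            for name, m in gs.structures.items()
        }
        cand = StructureSet("c1", "DL", cand_structs)
        import logging
        with caplog.at_level(logging.WARNING, logger="oareval.metrics"):
            df = results_to_dataframe(compare_structure_sets(cand, gs))
        assert "resampling" in caplog.text
        vd = df[df.metric == "VDSC"]
        assert (vd["value"] > 0.9).all()
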