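"""DVH engine, PTV expansion, evaluation-region rule and NPQM scoring."""

import numpy as np
import pytest

from oareval import (
    BinaryMask,
    DoseGrid,
    PQMObjective,
    PQMTemplate,
    StructureSet,
    VoxelGrid,
    cumulative_dvh,
    dose_stat,
    dosimetric_deltas,
    expand_ptv,
    mask_boolean,
    mask_volume_cc,
    npqm,
    oar_eval_region,
    pqm_score,
    translate_mask_voxels,
)
from oareval.errors import (
    EmptyTemplateError,
    InvalidParameterError,
    InvalidQueryError,
    UndefinedDVHError,
)

from conftest import cube_mask, sphere_mask
from oracles import brute_dilate


def full_body(grid):
    return BinaryMask(grid, np.ones(grid.shape, dtype=bool))


class TestExpandPtv:
    def test_zero_margin_is_ctv_within_body(self, iso_grid):
        ctv = cube_mask(iso_grid, (5, 5, 5), (6, 6, 6))
        body = cube_mask(iso_grid, (0, 0, 0), (24, 24, 8))
        ptv = expand_ptv(ctv, 0.0, body)
        expected = mask_boolean(ctv, body, "intersect")
        np.testing.assert_array_equal(ptv.occupancy, expected.occupancy)

    def test_matches_brute_force_euclidean_dilation(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 2), (20, 20, 12))
        ctv = cube_mask(grid, (6, 6, 3), (10, 10, 5))  # 10 mm cube
        ptv = expand_ptv(ctv, 3.0, full_body(grid))
        expected = brute_dilate(ctv.occupancy, grid.spacing, 3.0)
        np.testing.assert_array_equal(ptv.occupancy, expected)

    def test_extent_grows_three_voxels_on_1mm_grid(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (24, 24, 24))
        ctv = cube_mask(grid, (7, 7, 7), (10, 10, 10))
        ptv = expand_ptv(ctv, 3.0, full_body(grid))
        idx = np.argwhere(ptv.occupancy)
        assert idx[:, 0].min() == 4 and idx[:, 0].max() == 19

    def test_clipped_to_body_exactly(self, iso_grid):
        ctv = cube_mask(iso_grid, (0, 0, 0), (5, 5, 5))  # touches grid edge
        body = cube_mask(iso_grid, (2, 0, 0), (22, 24, 24))
        ptv = expand_ptv(ctv, 3.0, body)
        assert not ptv.occupancy[:2, :, :].any()

    def test_negative_margin_rejected(self, iso_grid):
        with pytest.raises(InvalidParameterError):
            expand_ptv(cube_mask(iso_grid, (1, 1, 1), (2, 2, 2)), -1.0,
                       full_body(iso_grid))


class TestEvalRegion:
    def test_disjoint_oar_untouched(self, iso_grid):
        oar = cube_mask(iso_grid, (2, 2, 2), (6, 6, 6))
        ptv = cube_mask(iso_grid, (15, 15, 15), (5, 5, 5))
        region = oar_eval_region(oar, [ptv])
        assert not region.excluded
        np.testing.assert_array_equal(region.mask.occupancy, oar.occupancy)

    def test_oar_inside_ptv_excluded(self, iso_grid):
        oar = cube_mask(iso_grid, (5, 5, 5), (3, 3, 3))
        ptv = cube_mask(iso_grid, (3, 3, 3), (8, 8, 8))
        region = oar_eval_region(oar, [ptv])
        assert region.excluded
        assert region.mask is None

    def test_point_one_cc_threshold_arithmetic(self):
        # 1 mm^3 voxels: OAR 250 voxels (0.25 cc), 200 overlap -> 0.05 cc < 0.1
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (20, 20, 20))
        oar = cube_mask(grid, (0, 0, 0), (5, 5, 10))          # 250 voxels
        ptv = cube_mask(grid, (0, 0, 0), (5, 5, 8))           # overlap 200
        region = oar_eval_region(oar, [ptv])
        assert region.volume_cc == pytest.approx(0.05)
        assert region.excluded

    def test_region_above_threshold_survives(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (20, 20, 20))
        oar = cube_mask(grid, (0, 0, 0), (5, 5, 10))
        ptv = cube_mask(grid, (0, 0, 0), (5, 5, 4))           # leaves 0.15 cc
        region = oar_eval_region(oar, [ptv])
        assert not region.excluded
        assert region.volume_cc == pytest.approx(0.15)


class TestDVH:
    def test_uniform_dose_step_curve(self, iso_grid):
        region = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        dose = DoseGrid(iso_grid, np.full(iso_grid.shape, 60.0))
        curve = cumulative_dvh(region, dose)
        v = mask_volume_cc(region)
        assert curve.volume_at_or_above(0.0) == pytest.approx(v)
        assert curve.volume_at_or_above(60.0) == pytest.approx(v)
        assert curve.volume_at_or_above(60.0 + 1e-9) == 0.0

    def test_two_voxel_hand_computation(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 2), (4, 4, 4))  # 2 mm3 voxels
        occ = np.zeros(grid.shape, dtype=bool)
        occ[0, 0, 0] = occ[1, 0, 0] = True
        dose_arr = np.zeros(grid.shape)
        dose_arr[0, 0, 0], dose_arr[1, 0, 0] = 10.0, 20.0
        curve = cumulative_dvh(BinaryMask(grid, occ), DoseGrid(grid, dose_arr))
        assert curve.volume_at_or_above(10.0) == pytest.approx(0.004)
        assert curve.volume_at_or_above(20.0) == pytest.approx(0.002)

    def test_volume_conservation_random_inputs(self, iso_grid):
        rng = np.random.default_rng(4)
        for _ in range(5):
            occ = rng.random(iso_grid.shape) > 0.7
            if not occ.any():
                continue
            region = BinaryMask(iso_grid, occ)
            dose = DoseGrid(iso_grid, rng.random(iso_grid.shape) * 70)
            curve = cumulative_dvh(region, dose)
            assert curve.total_volume_cc == pytest.approx(mask_volume_cc(region))
            assert curve.volume_at_or_above(0.0) == pytest.approx(
                mask_volume_cc(region)
            )

    def test_empty_region_undefined(self, iso_grid):
        with pytest.raises(UndefinedDVHError):
            cumulative_dvh(BinaryMask.empty(iso_grid),
                           DoseGrid(iso_grid, np.zeros(iso_grid.shape)))


class TestDoseStat:
    def test_uniform_dose_stats(self, iso_grid):
        region = cube_mask(iso_grid, (2, 2, 2), (6, 6, 6))
        curve = cumulative_dvh(region, DoseGrid(iso_grid, np.full(iso_grid.shape, 54.0)))
        assert dose_stat(curve, "Dmean") == pytest.approx(54.0)
        assert dose_stat(curve, "D0.03cc") == pytest.approx(54.0)

    def test_linear_ramp_mean_is_midpoint(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (61, 10, 10))
        ramp = np.broadcast_to(
            np.arange(61.0)[:, None, None], grid.shape
        ).copy()  # 0..60 Gy along x
        region = cube_mask(grid, (0, 0, 0), (61, 10, 10))
        curve = cumulative_dvh(region, DoseGrid(grid, ramp))
        assert dose_stat(curve, "Dmean") == pytest.approx(30.0, abs=0.5)

    def test_hot_voxel_smaller_than_query_volume(self):
        # hottest voxels occupy 0.05 cc at 70 Gy -> D0.03cc = 70
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (10, 10, 10))
        occ = np.zeros(grid.shape, dtype=bool)
        occ[:5, :5, :8] = True
        dose_arr = np.full(grid.shape, 30.0)
        dose_arr[0, 0, :5] = 70.0  # 50 mm3? no: 5 voxels = 0.005 cc
        dose_arr[0, :5, :2] = 70.0
        dose_arr[1, :5, :4] = 70.0
        dose_arr[2, :5, :4] = 70.0
        # total 70 Gy voxels >= 0.03 cc guaranteed: make exactly 50 voxels hot
        dose_arr = np.full(grid.shape, 30.0)
        hot = np.argwhere(occ)[:50]
        dose_arr[tuple(hot.T)] = 70.0
        curve = cumulative_dvh(BinaryMask(grid, occ), DoseGrid(grid, dose_arr))
        assert dose_stat(curve, "D0.03cc") == pytest.approx(70.0)

    def test_vgy_volume_query(self, iso_grid):
        region = cube_mask(iso_grid, (0, 0, 0), (10, 10, 10))
        dose_arr = np.zeros(iso_grid.shape)
        dose_arr[:10, :10, :5] = 50.0
        curve = cumulative_dvh(region, DoseGrid(iso_grid, dose_arr))
        assert dose_stat(curve, "V50Gy") == pytest.approx(0.5)

    def test_dxcc_beyond_volume_rejected(self, iso_grid):
        region = cube_mask(iso_grid, (0, 0, 0), (2, 2, 2))
        curve = cumulative_dvh(region, DoseGrid(iso_grid, np.ones(iso_grid.shape)))
        with pytest.raises(InvalidQueryError):
            dose_stat(curve, "D100cc")

    def test_d_hottest_non_increasing_in_volume(self, iso_grid):
        rng = np.random.default_rng(8)
        region = cube_mask(iso_grid, (0, 0, 0), (10, 10, 10))
        curve = cumulative_dvh(
            region, DoseGrid(iso_grid, rng.random(iso_grid.shape) * 70)
        )
        vols = [0.01, 0.03, 0.1, 0.5, 1.0]
        ds = [curve.dose_to_hottest(v) for v in vols]
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))


def _simple_template():
    return PQMTemplate(
        [
            PQMObjective("OAR_A", "Dmean", "<=", 20.0, 1.0),
            PQMObjective("OAR_B", "Dmean", "<=", 20.0, 1.0),
        ],
        template_id="toy",
    )


class TestPQM:
    def _setup(self, iso_grid, dose_a=10.0, dose_b=10.0):
        a = cube_mask(iso_grid, (2, 2, 2), (5, 5, 5))
        b = cube_mask(iso_grid, (12, 12, 12), (5, 5, 5))
        structs = StructureSet("c1", "GS", {"OAR_A": a, "OAR_B": b})
        dose_arr = np.zeros(iso_grid.shape)
        dose_arr[a.occupancy] = dose_a
        dose_arr[b.occupancy] = dose_b
        return structs, DoseGrid(iso_grid, dose_arr)

    def test_all_satisfied_full_score(self, iso_grid):
        structs, dose = self._setup(iso_grid)
        achieved, maximum = pqm_score(structs, dose, _simple_template())
        assert achieved == maximum == 2.0
        assert npqm(structs, dose, _simple_template()) == 100.0

    def test_all_violated_zero(self, iso_grid):
        structs, dose = self._setup(iso_grid, 60.0, 60.0)
        achieved, maximum = pqm_score(structs, dose, _simple_template())
        assert achieved == 0.0 and maximum == 2.0

    def test_half_met_gives_50(self, iso_grid):
        structs, dose = self._setup(iso_grid, 10.0, 60.0)
        assert npqm(structs, dose, _simple_template()) == 50.0

    def test_ramp_midway_half_points(self, iso_grid):
        structs, dose = self._setup(iso_grid, 25.0, 10.0)
        tmpl = PQMTemplate([
            PQMObjective("OAR_A", "Dmean", "<=", 20.0, 2.0, zero_threshold=30.0),
        ])
        achieved, maximum = pqm_score(structs, dose, tmpl)
        assert achieved == pytest.approx(1.0)  # exactly midway -> half of 2 points
        assert maximum == 2.0

    def test_absent_structure_leaves_normalization(self, iso_grid):
        structs, dose = self._setup(iso_grid, 10.0, 10.0)
        partial = StructureSet("c1", "DL", {
            "OAR_A": structs.get("OAR_A"), "OAR_B": None,
        })
        # both objectives would score at the overall ratio -> NPQM unchanged
        assert npqm(partial, dose, _simple_template()) == pytest.approx(
            npqm(structs, dose, _simple_template())
        )

    def test_template_of_only_absent_structures_is_error(self, iso_grid):
        structs, dose = self._setup(iso_grid)
        ghost = PQMTemplate([PQMObjective("Nothing", "Dmean", "<=", 10.0, 1.0)])
        with pytest.raises(EmptyTemplateError):
            pqm_score(structs, dose, ghost)

    def test_invalid_ramp_rejected(self):
        with pytest.raises(InvalidParameterError):
            PQMObjective("X", "Dmean", "<=", 20.0, 1.0, zero_threshold=15.0)

    def test_achieved_never_exceeds_maximum(self, iso_grid):
        rng = np.random.default_rng(6)
        structs, _ = self._setup(iso_grid)
        for _ in range(5):
            dose = DoseGrid(iso_grid, rng.random(iso_grid.shape) * 60)
            achieved, maximum = pqm_score(structs, dose, _simple_template())
            assert 0.0 <= achieved <= maximum


class TestDosimetricDeltas:
    def _case(self, shift_voxels=(0, 0, 0)):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (40, 20, 20))
        oar = cube_mask(grid, (10, 6, 6), (8, 8, 8))
        gs = StructureSet("c1", "GS", {"OAR_A": oar})
        arm = StructureSet("c1", "DL",
                           {"OAR_A": translate_mask_voxels(oar, shift_voxels)})
        ramp = np.broadcast_to(
            np.arange(40.0)[:, None, None] * 1.5, grid.shape
        ).copy()  # 1.5 Gy/mm along x
        return gs, arm, DoseGrid(grid, ramp)

    def test_identical_arm_all_deltas_zero(self, iso_grid):
        gs, arm, dose = self._case()
        tmpl = PQMTemplate([PQMObjective("OAR_A", "Dmean", "<=", 30.0, 1.0)])
        df, dnpqm = dosimetric_deltas(arm, gs, dose, template=tmpl)
        assert (df["value"] == 0.0).all()
        assert dnpqm == 0.0

    def test_shift_into_ramp_matches_gradient(self):
        gs, arm, dose = self._case(shift_voxels=(4, 0, 0))
        df, _ = dosimetric_deltas(arm, gs, dose)
        dmean = df.loc[df.metric == "abs_dDmean_Gy", "value"].iloc[0]
        # 4 mm shift x 1.5 Gy/mm = 6 Gy
        assert dmean == pytest.approx(6.0, abs=0.1)

    def test_structure_excluded_in_one_set_skipped(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (30, 30, 30))
        oar = cube_mask(grid, (2, 2, 2), (4, 4, 4))
        gs = StructureSet("c1", "GS", {"OAR_A": oar})
        # arm version sits inside the PTV -> excluded there only
        arm = StructureSet("c1", "DL", {"OAR_A": translate_mask_voxels(oar, (13, 13, 13))})
        ptv = cube_mask(grid, (12, 12, 12), (12, 12, 12))
        dose = DoseGrid(grid, np.full(grid.shape, 10.0))
        df, _ = dosimetric_deltas(arm, gs, dose, ptvs=[ptv])
        assert len(df) == 0
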