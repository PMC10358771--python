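import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from contourqa import oracle
from contourqa.metrics import (
    MetricConfig,
    apl,
    dsc,
    evaluate_pair,
    evaluate_single,
    extract_surface,
    hd95,
    mda,
    pvd,
    rapl,
    sdsc,
)
from contourqa.phantoms import PerturbationSpec, perturb
from contourqa.volume import BinaryMask, StructureSet

from conftest import cube_mask, random_blob_pair


def shifted(mask: BinaryMask, mm: float) -> BinaryMask:
    return perturb(mask, PerturbationSpec("translate_mm", mm)).mask


class TestDsc:
    def test_identical_masks(self):
        m = cube_mask(6)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = cube_mask(3, offset=(0, 0, 0))
        b = cube_mask(3, offset=(9, 9, 9))
        assert dsc(a, b) == 0.0

    def test_shifted_cube_analytic_overlap(self):
        ref = cube_mask(10)
        assert dsc(shifted(ref, 2.0), ref) == pytest.approx(0.8)

    def test_both_empty_is_one(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert dsc(e, e) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(bool, (5, 5, 4)), hnp.arrays(bool, (5, 5, 4)))
    def test_symmetric_and_bounded(self, a, b):
        ma = BinaryMask(a, (1, 1, 2))
        mb = BinaryMask(b, (1, 1, 2))
        v = dsc(ma, mb)
        assert v == dsc(mb, ma)
        assert 0.0 <= v <= 1.0


class TestSurfaceExtraction:
    def test_single_voxel_six_unit_faces(self):
        m = BinaryMask(np.ones((1, 1, 1), bool), (1, 1, 1))
        s = extract_surface(m)
        assert len(s.areas) == 6
        assert s.total_area == pytest.approx(6.0)

    def test_cube_2x2x2_area(self):
        m = cube_mask(2, grid=(4, 4, 4), offset=(1, 1, 1))
        assert extract_surface(m).total_area == pytest.approx(24.0)

    def test_anisotropic_cube_area_formula(self):
        dx, dz = 1.1875, 3.0
        m = cube_mask(10, grid=(14, 14, 14), spacing=(dx, dx, dz), offset=(2, 2, 2))
        expected = 2 * (10 * dx) ** 2 + 4 * (10 * dx) * (10 * dz)
        assert extract_surface(m).total_area == pytest.approx(expected)

    def test_matches_bruteforce_enumeration(self, rng):
        a, _ = random_blob_pair(rng)
        fast = extract_surface(a)
        pts, areas = oracle.brute_surface(a)
        # same multiset of (point, area) pairs
        fast_sorted = np.lexsort(fast.points.T)
        brute_sorted = np.lexsort(pts.T)
        np.testing.assert_allclose(fast.points[fast_sorted], pts[brute_sorted])
        np.testing.assert_allclose(fast.areas[fast_sorted], areas[brute_sorted])

    def test_empty_mask_empty_surface(self):
        m = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        assert extract_surface(m).is_empty()


class TestDistanceMetrics:
    def test_identical_masks_all_zero(self):
        m = cube_mask(6)
        assert mda(m, m) == 0.0
        assert hd95(m, m) == 0.0

    def test_two_voxels_along_z(self):
        data = np.zeros((3, 3, 9), bool)
        data[1, 1, 1] = True
        a = BinaryMask(data, (1, 1, 3))
        data2 = np.zeros((3, 3, 9), bool)
        data2[1, 1, 6] = True
        b = BinaryMask(data2, (1, 1, 3))
        # 5 voxels apart at dz = 3 mm; exact value fixed by brute force
        assert mda(a, b) == pytest.approx(oracle.brute_mda(a, b), abs=1e-9)
        got = hd95(a, b, MetricConfig(hd_percentile=100))
        assert got == pytest.approx(oracle.brute_hd(a, b, 100), abs=1e-9)
        assert got == pytest.approx(15.0, abs=3.0)  # face-offset convention

    def test_exact_hausdorff_of_shifted_cube(self):
        ref = cube_mask(10, grid=(16, 16, 16))
        auto = shifted(ref, 2.0)
        assert hd95(auto, ref, MetricConfig(hd_percentile=100)) == pytest.approx(2.0)

    def test_mda_symmetric(self, rng):
        a, b = random_blob_pair(rng)
        # symmetric by construction; summation order costs at most an ulp
        assert mda(a, b) == pytest.approx(mda(b, a), rel=1e-14)

    def test_hd95_at_least_mda(self, rng):
        for _ in range(30):
            a, b = random_blob_pair(rng)
            assert hd95(a, b) >= mda(a, b) - 1e-12

    def test_pooled_convention_matches_bruteforce(self, rng):
        cfg = MetricConfig(hd_convention="pooled")
        a, b = random_blob_pair(rng)
        assert hd95(a, b, cfg) == pytest.approx(
            oracle.brute_hd(a, b, 95, "pooled"), abs=1e-9)

    def test_empty_mask_raises(self):
        m = cube_mask(4)
        e = BinaryMask(np.zeros(m.shape, bool), m.spacing)
        with pytest.raises(ValueError, match="empty"):
            mda(e, m)


class TestPvd:
    def test_sign_convention_underdrawn_negative(self):
        ref = cube_mask(10, grid=(12, 12, 12), offset=(1, 1, 1))
        auto = ref.with_data(ref.data & (np.arange(12)[None, None, :] < 10))
        # 10x10x9 vs 10x10x10 -> -10%
        assert pvd(auto, ref) == pytest.approx(-10.0)

    def test_identical_masks_zero(self):
        m = cube_mask(5)
        assert pvd(m, m) == 0.0

    def test_full_dilation_of_cube(self):
        ref = cube_mask(10, grid=(16, 16, 16))
        auto = perturb(ref, PerturbationSpec("dilate_voxels", 1,
                                             structure="box")).mask
        assert pvd(auto, ref) == pytest.approx(100 * (12**3 - 10**3) / 10**3)

    def test_empty_reference_undefined(self):
        m = cube_mask(4)
        e = BinaryMask(np.zeros(m.shape, bool), m.spacing)
        with pytest.raises(ValueError):
            pvd(m, e)


class TestSurfaceDice:
    def test_identical_masks_any_tolerance(self):
        m = cube_mask(6)
        for tol in (0.0, 1.0, 5.0):
            assert sdsc(m, m, MetricConfig(tolerance_mm=tol)) == 1.0

    def test_far_apart_masks_zero(self):
        a = cube_mask(3, offset=(0, 0, 0))
        b = cube_mask(3, offset=(10, 10, 10))
        assert sdsc(a, b) == 0.0

    def test_sub_tolerance_shift_is_perfect(self):
        ref = cube_mask(10, grid=(16, 16, 16))
        assert sdsc(shifted(ref, 1.0), ref) == 1.0

    def test_supra_tolerance_shift_matches_bruteforce(self):
        ref = cube_mask(10, grid=(18, 18, 18))
        auto = shifted(ref, 5.0)
        assert sdsc(auto, ref) == pytest.approx(
            oracle.brute_sdsc(auto, ref, 2.0), abs=1e-9)

    def test_tolerance_limits(self, rng):
        a, b = random_blob_pair(rng)
        assert sdsc(a, b, MetricConfig(tolerance_mm=1e6)) == 1.0
        coincident = sdsc(a, b, MetricConfig(tolerance_mm=0.0))
        assert coincident == pytest.approx(
            oracle.brute_sdsc(a, b, 0.0), abs=1e-9)


class TestAddedPathLength:
    def test_identical_masks_zero(self):
        m = cube_mask(6)
        assert apl(m, m) == 0.0

    def test_missing_auto_full_perimeter(self):
        k = 4
        ref = cube_mask(10, grid=(14, 14, 8), offset=(2, 2, 2))
        ref = ref.with_data(ref.data & (np.arange(8)[None, None, :] < 2 + k))
        auto = ref.with_data(np.zeros(ref.shape, bool))
        assert apl(auto, ref) == pytest.approx(k * 40.0)

    def test_sub_tolerance_shift_needs_no_edits(self):
        ref = cube_mask(10, grid=(16, 16, 16))
        assert apl(shifted(ref, 1.0), ref) == 0.0

    def test_supra_tolerance_shift_matches_bruteforce(self):
        ref = cube_mask(10, grid=(18, 18, 18))
        auto = shifted(ref, 5.0)
        assert apl(auto, ref) == pytest.approx(
            oracle.brute_apl_slice2d(auto, ref, 2.0), abs=1e-9)

    def test_surface3d_mode_reports_area(self):
        ref = cube_mask(10, grid=(18, 18, 18))
        auto = shifted(ref, 5.0)
        cfg = MetricConfig(apl_mode="surface3d")
        a3d = apl(auto, ref, cfg)
        assert a3d > 0
        # rAPL ignores the 3D mode and keeps mm/cc units
        assert rapl(auto, ref, cfg) == pytest.approx(
            apl(auto, ref) / ref.volume_cc)

    def test_reference_anchored_asymmetry(self):
        ref = cube_mask(10, grid=(18, 18, 18))
        auto = perturb(ref, PerturbationSpec("erode_voxels", 3)).mask
        assert apl(auto, ref) != apl(ref, auto)


class TestRapl:
    def test_definition(self):
        ref = cube_mask(10, grid=(16, 16, 16))
        auto = shifted(ref, 5.0)
        assert rapl(auto, ref) == pytest.approx(apl(auto, ref) / ref.volume_cc)
        assert rapl(ref, ref) == 0.0

    def test_volume_scaling_halves_rapl(self):
        # same 5 mm boundary error on an 8x larger organ: APL ~4x, volume 8x
        small_ref = cube_mask(10, grid=(20, 20, 20), offset=(2, 2, 2))
        big_ref = cube_mask(20, grid=(32, 32, 32), offset=(4, 4, 4))
        r_small = rapl(shifted(small_ref, 5.0), small_ref)
        r_big = rapl(shifted(big_ref, 5.0), big_ref)
        assert r_big == pytest.approx(0.5 * r_small, rel=0.25)


class TestInvariantsAndProperties:
    def test_spacing_scaling_is_linear_for_distances(self, rng):
        a, b = random_blob_pair(rng, spacing=(1.0, 1.0, 2.0))
        a2 = BinaryMask(a.data, (2.0, 2.0, 4.0))
        b2 = BinaryMask(b.data, (2.0, 2.0, 4.0))
        assert mda(a2, b2) == pytest.approx(2 * mda(a, b), rel=1e-9)
        assert hd95(a2, b2) == pytest.approx(2 * hd95(a, b), rel=1e-9)
        assert dsc(a2, b2) == dsc(a, b)
        assert sdsc(a2, b2, MetricConfig(tolerance_mm=4.0)) == pytest.approx(
            sdsc(a, b, MetricConfig(tolerance_mm=2.0)), rel=1e-9)

    def test_monotone_under_nested_erosion(self):
        ref = cube_mask(12, grid=(20, 20, 20), offset=(4, 4, 4))
        prev_dsc, prev_sdsc, prev_apl = 1.0, 1.0, 0.0
        for k in (1, 2, 3, 4):
            auto = perturb(ref, PerturbationSpec("erode_voxels", k)).mask
            d, s = dsc(auto, ref), sdsc(auto, ref)
            a = apl(auto, ref)
            assert d <= prev_dsc + 1e-12
            assert s <= prev_sdsc + 1e-12
            assert a >= prev_apl - 1e-12
            prev_dsc, prev_sdsc, prev_apl = d, s, a

    def test_oracle_equivalence_on_random_pairs(self, rng):
        """Fast KD-tree metrics equal all-pairs brute force to 1e-6 mm."""
        cfg = MetricConfig()
        for _ in range(40):
            a, b = random_blob_pair(rng)
            assert mda(a, b) == pytest.approx(oracle.brute_mda(a, b), abs=1e-6)
            assert hd95(a, b, cfg) == pytest.approx(
                oracle.brute_hd(a, b, 95), abs=1e-6)
            assert sdsc(a, b, cfg) == pytest.approx(
                oracle.brute_sdsc(a, b, 2.0), abs=1e-6)
            assert apl(a, b, cfg) == pytest.approx(
                oracle.brute_apl_slice2d(a, b, 2.0), abs=1e-6)


class TestEvaluatePair:
    def test_perfect_twelve_organ_phantom(self, clean_phantom):
        _, structures, _ = clean_phantom
        results = evaluate_pair(structures, structures)
        assert len(results) == 12
        for res in results.values():
            assert res.dsc == 1.0
            assert res.sdsc == 1.0
            assert res.mda_mm == 0.0
            assert res.hd95_mm == 0.0
            assert res.apl_mm == 0.0
            assert res.pvd_pct == 0.0

    def test_missing_organ_is_flagged_not_zeroed(self):
        ref = cube_mask(6)
        empty = ref.with_data(np.zeros(ref.shape, bool))
        res = evaluate_single(empty, ref)
        assert res.dsc == 0.0
        assert res.pvd_pct == pytest.approx(-100.0)
        assert res.mda_mm is None and res.hd95_mm is None and res.sdsc is None
        assert "empty_auto" in res.flags
        assert res.apl_mm == pytest.approx(apl(empty, ref))
        assert res.apl_mm > 0

    def test_one_missing_organ_does_not_poison_others(self):
        ref_a, ref_b = cube_mask(6), cube_mask(4, offset=(9, 9, 9))
        ref = StructureSet({"a": ref_a, "b": ref_b})
        auto = StructureSet({"a": ref_a,
                             "b": ref_b.with_data(np.zeros(ref_b.shape, bool))})
        results = evaluate_pair(auto, ref)
        assert results["a"].dsc == 1.0 and results["a"].flags == ()
        assert "empty_auto" in results["b"].flags

    def test_organ_name_mismatch_lists_difference(self):
        m = cube_mask(4)
        with pytest.raises(ValueError, match="liver"):
            evaluate_pair(StructureSet({"liver": m}), StructureSet({"spleen": m}))
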