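"""Contact-geometry unit and property tests against analytic shapes and the
brute-force oracle."""

import numpy as np
import pytest

from capcontact import geometry as G
from capcontact import oracle as O
from capcontact.volume import SegmentationVolume, IntensityVolume

from conftest import make_cuboid, make_sphere, make_cylinder, random_phantom_pair


class TestCapsuleSurface:
    def test_cube_surface_area_exact(self):
        v = make_cuboid((7, 7, 7), (2, 2, 2), (5, 5, 5))
        assert G.extract_capsule_surface(v).total_area_mm2 == pytest.approx(54.0)

    def test_fine_grid_cube_exact(self):
        # 10 mm cube sampled at 0.5 mm: face counting is exact for cuboids
        v = make_cuboid((24, 24, 24), (2, 2, 2), (22, 22, 22),
                        spacing=(0.5, 0.5, 0.5))
        assert G.extract_capsule_surface(v).total_area_mm2 == pytest.approx(600.0)

    def test_anisotropic_face_areas(self):
        v = make_cuboid((6, 6, 6), (1, 1, 1), (4, 4, 4), spacing=(1, 2, 3))
        cap = G.extract_capsule_surface(v)
        # 3x3x3 voxel cube: 9 faces per side; x-faces 2*3, y-faces 1*3, z-faces 1*2
        expected = 2 * 9 * (2 * 3 + 1 * 3 + 1 * 2)
        assert cap.total_area_mm2 == pytest.approx(expected)

    def test_empty_mask_raises(self):
        v = SegmentationVolume(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            G.extract_capsule_surface(v)

    def test_two_components_raise_with_count(self):
        m = np.zeros((9, 9, 9), bool)
        m[1:3, 1:3, 1:3] = True
        m[6:8, 6:8, 6:8] = True
        with pytest.raises(ValueError, match="found 2"):
            G.extract_capsule_surface(SegmentationVolume(m, (1, 1, 1)))


class TestDistanceMap:
    def test_slab_interior_distance(self):
        slab = make_cuboid((20, 20, 10), (0, 0, 0), (20, 20, 10))
        cap = G.extract_capsule_surface(slab)
        d = G.capsule_distance_map(slab.shape, slab.spacing_mm, cap)
        # voxel 3 layers from the bottom axial face, centered in-plane
        assert d[10, 10, 3] == pytest.approx(3.0, abs=0.5)

    def test_matches_oracle_anisotropic(self, rng):
        prostate, _ = random_phantom_pair(rng, max_grid=26)
        cap = G.extract_capsule_surface(prostate)
        fast = G.capsule_distance_map(prostate.shape, prostate.spacing_mm, cap)
        slow = O.oracle_distance_map(prostate.shape, prostate.spacing_mm,
                                     cap.positions_mm)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_anisotropic_step_reflected(self):
        v = make_cuboid((12, 12, 8), (0, 0, 2), (12, 12, 6), spacing=(1, 1, 3))
        cap = G.extract_capsule_surface(v)
        d = G.capsule_distance_map(v.shape, v.spacing_mm, cap)
        # one voxel step along the coarse axis moves 3 mm away from the face
        assert d[6, 6, 3] - d[6, 6, 2] == pytest.approx(3.0, abs=1e-9)

    def test_mirror_symmetry(self, rng):
        prostate, _ = random_phantom_pair(rng, max_grid=26)
        cap = G.extract_capsule_surface(prostate)
        d = G.capsule_distance_map(prostate.shape, prostate.spacing_mm, cap)
        flipped = SegmentationVolume(prostate.voxels[::-1], prostate.spacing_mm)
        cap_f = G.extract_capsule_surface(flipped)
        d_f = G.capsule_distance_map(flipped.shape, flipped.spacing_mm, cap_f)
        assert np.allclose(d, d_f[::-1], atol=1e-9)


class TestContactLength:
    def test_no_contact_when_interior(self):
        prostate = make_cuboid((30, 30, 30), (0, 0, 0), (30, 30, 30))
        lesion = make_cuboid((30, 30, 30), (13, 13, 13), (17, 17, 17))
        cap = G.extract_capsule_surface(prostate)
        assert G.tumor_contact_length(lesion, cap, 1.0) == 0.0

    def test_cylinder_arc_length(self):
        # 20 mm radius cylinder; lesion hugging a 30-degree arc centered on +x
        prostate = make_cylinder((50, 50, 7), (24.5, 24.5), 20.0)
        x = np.arange(50)[:, None] - 24.5
        y = np.arange(50)[None, :] - 24.5
        r = np.hypot(x, y)
        ang = np.degrees(np.arctan2(y, x))
        wedge = (r <= 20.0) & (r >= 16.0) & (np.abs(ang) <= 15.0)
        lesion_mask = np.zeros((50, 50, 7), bool)
        lesion_mask[:, :, 3] = wedge
        lesion = SegmentationVolume(lesion_mask, (1, 1, 1))
        cap = G.extract_capsule_surface(prostate)
        tcl = G.tumor_contact_length(lesion, cap, 1.0)
        expected = 20.0 * np.pi / 6
        assert tcl == pytest.approx(expected, rel=0.15)

    def test_scaling_doubles_tcl(self, rng):
        prostate, lesion = random_phantom_pair(rng, max_grid=28)
        cap = G.extract_capsule_surface(prostate)
        t1 = G.tumor_contact_length(lesion, cap, 1.0)
        p2 = SegmentationVolume(prostate.voxels, prostate.spacing_mm * 2)
        l2 = SegmentationVolume(lesion.voxels, lesion.spacing_mm * 2)
        cap2 = G.extract_capsule_surface(p2)
        t2 = G.tumor_contact_length(l2, cap2, 2.0)  # thresholds are lengths too
        assert t2 == pytest.approx(2 * t1, abs=1e-9)


class TestContactSurfaceArea:
    def test_planar_face_contact(self):
        prostate = make_cuboid((20, 20, 20), (2, 2, 2), (18, 18, 18))
        lesion = make_cuboid((20, 20, 20), (2, 5, 5), (7, 15, 15))
        cap = G.extract_capsule_surface(prostate)
        tcsa = G.contact_surface_area(lesion, cap, 1.0)
        assert tcsa == pytest.approx(100.0, rel=0.10)

    def test_whole_prostate_lesion_covers_capsule(self):
        prostate = make_cuboid((12, 12, 12), (2, 2, 2), (10, 10, 10))
        cap = G.extract_capsule_surface(prostate)
        tcsa = G.contact_surface_area(prostate, cap, 5.0)
        assert tcsa == pytest.approx(cap.total_area_mm2)

    def test_monotone_in_distance(self, rng):
        for _ in range(5):
            prostate, lesion = random_phantom_pair(rng, max_grid=28)
            cap = G.extract_capsule_surface(prostate)
            vals = [G.contact_surface_area(lesion, cap, d)
                    for d in (1.0, 3.0, 5.0)]
            assert vals[0] <= vals[1] <= vals[2]
            assert vals[2] <= cap.total_area_mm2 + 1e-9

    def test_nonpositive_distance_rejected(self):
        prostate = make_cuboid((8, 8, 8), (2, 2, 2), (6, 6, 6))
        cap = G.extract_capsule_surface(prostate)
        with pytest.raises(ValueError, match="positive"):
            G.contact_surface_area(prostate, cap, 0.0)


class TestContactVolume:
    def test_cuboid_against_planar_capsule(self):
        prostate = make_cuboid((24, 24, 24), (2, 2, 2), (22, 22, 22))
        lesion = make_cuboid((24, 24, 24), (2, 6, 6), (12, 16, 16))
        cap = G.extract_capsule_surface(prostate)
        tcv = G.contact_volume(lesion, cap, 2.0)
        assert tcv == pytest.approx(200.0, rel=0.10)

    def test_deep_interior_lesion_zero(self):
        prostate = make_cuboid((30, 30, 30), (1, 1, 1), (29, 29, 29))
        lesion = make_cuboid((30, 30, 30), (13, 13, 13), (17, 17, 17))
        cap = G.extract_capsule_surface(prostate)
        assert G.contact_volume(lesion, cap, 5.0) == 0.0

    def test_bounded_by_lesion_volume(self, rng):
        for _ in range(5):
            prostate, lesion = random_phantom_pair(rng, max_grid=28)
            cap = G.extract_capsule_surface(prostate)
            assert G.contact_volume(lesion, cap, 5.0) <= lesion.volume_mm3() + 1e-9


class TestShapeFeatures:
    def test_sphere_volume_and_diameter(self):
        lesion = make_sphere((16, 16, 16), (7, 7, 7), 5.0)
        vol, diam = G.lesion_shape_features(lesion)
        assert vol == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)
        assert diam == pytest.approx(10.0, abs=np.sqrt(3))

    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        vol, diam = G.lesion_shape_features(SegmentationVolume(m, (1, 1, 1)))
        assert vol == 1.0 and diam == 0.0

    def test_disconnected_lesion_rejected(self):
        m = np.zeros((9, 9, 9), bool)
        m[1, 1, 1] = True
        m[7, 7, 7] = True
        with pytest.raises(ValueError, match="component"):
            G.lesion_shape_features(SegmentationVolume(m, (1, 1, 1)))


class TestAdcStatistics:
    def test_forced_values(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, :3] = True
        vals = np.zeros((3, 3, 3))
        vals[0, 0, :3] = [600, 700, 800]
        mean, med, p10, mn = G.adc_statistics(
            IntensityVolume(vals, (1, 1, 1)), SegmentationVolume(m, (1, 1, 1)))
        assert mean == 700 and med == 700 and mn == 600

    def test_constant_volume(self):
        m = np.ones((3, 3, 3), bool)
        stats = G.adc_statistics(IntensityVolume(np.full((3, 3, 3), 950.0),
                                                 (1, 1, 1)),
                                 SegmentationVolume(m, (1, 1, 1)))
        assert all(s == 950.0 for s in stats)

    def test_percentile_convention(self):
        # linear interpolation: values 1..100 -> p10 = 10.9
        m = np.zeros((10, 10, 1), bool)
        m[:, :, 0] = True
        vals = np.arange(1, 101, dtype=float).reshape(10, 10, 1)
        _, _, p10, _ = G.adc_statistics(IntensityVolume(vals, (1, 1, 1)),
                                        SegmentationVolume(m, (1, 1, 1)))
        assert p10 == pytest.approx(10.9)


class TestFeatureVector:
    def test_matches_oracle_on_phantom(self, rng):
        prostate, lesion = random_phantom_pair(rng, max_grid=28)
        fv = G.extract_feature_vector(prostate, lesion)
        half_voxel = 0.5 * max(prostate.spacing_mm)
        truth = O.oracle_lesion_truth(prostate, lesion)
        for d in (1.0, 3.0, 5.0):
            assert fv.tcsa_mm2[d] == pytest.approx(
                truth[f"true_tcsa_{d:g}mm_mm2"], abs=1e-9)
            assert fv.tcv_mm3[d] == pytest.approx(
                truth[f"true_tcv_{d:g}mm_mm3"], abs=1e-9)
        assert fv.tcl_mm == pytest.approx(truth["true_tcl_mm"], abs=1e-9)
        assert fv.lesion_volume_mm3 == truth["true_volume_mm3"]
        assert fv.lesion_diameter_mm == pytest.approx(
            truth["true_diameter_mm"], abs=half_voxel)

    def test_missing_adc_flagged(self, rng):
        prostate, lesion = random_phantom_pair(rng, max_grid=24)
        fv = G.extract_feature_vector(prostate, lesion, adc=None)
        assert not fv.adc_available
        assert np.isnan(fv.adc_mean)
        assert fv.lesion_volume_mm3 > 0

    def test_lesion_outside_prostate_rejected(self):
        prostate = make_cuboid((20, 20, 20), (2, 2, 2), (10, 10, 10))
        lesion = make_cuboid((20, 20, 20), (14, 14, 14), (18, 18, 18))
        with pytest.raises(ValueError, match="outside"):
            G.extract_feature_vector(prostate, lesion)


class TestInvariants:
    def test_oracle_equivalence_randomized(self, rng):
        for _ in range(8):
            prostate, lesion = random_phantom_pair(rng, max_grid=30)
            cap = G.extract_capsule_surface(prostate)
            half_voxel = 0.5 * max(prostate.spacing_mm)
            for d in (1.0, 5.0):
                assert G.contact_surface_area(lesion, cap, d) == pytest.approx(
                    O.oracle_tcsa(lesion, prostate, d), abs=1e-9)
                assert G.contact_volume(lesion, cap, d) == pytest.approx(
                    O.oracle_tcv(lesion, prostate, d), abs=1e-9)
            assert G.tumor_contact_length(lesion, cap, 1.0) == pytest.approx(
                O.oracle_tcl(lesion, prostate, 1.0), abs=1e-9)
            del half_voxel

    def test_scaling_laws(self, rng):
        prostate, lesion = random_phantom_pair(rng, max_grid=28)
        cap1 = G.extract_capsule_surface(prostate)
        s = 2.0
        p2 = SegmentationVolume(prostate.voxels, prostate.spacing_mm * s)
        l2 = SegmentationVolume(lesion.voxels, lesion.spacing_mm * s)
        cap2 = G.extract_capsule_surface(p2)
        for d in (2.0, 5.0):
            assert G.contact_surface_area(l2, cap2, s * d) == pytest.approx(
                s ** 2 * G.contact_surface_area(lesion, cap1, d), rel=1e-9)
            assert G.contact_volume(l2, cap2, s * d) == pytest.approx(
                s ** 3 * G.contact_volume(lesion, cap1, d), rel=1e-9)
        v1, d1 = G.lesion_shape_features(lesion)
        v2, d2 = G.lesion_shape_features(l2)
        assert v2 == pytest.approx(s ** 3 * v1) and d2 == pytest.approx(s * d1)

    def test_translation_invariance(self, rng):
        prostate, lesion = random_phantom_pair(rng, max_grid=26)
        cap = G.extract_capsule_surface(prostate)
        shift = np.array([1, 2, 1])
        pv = np.roll(prostate.voxels, shift, axis=(0, 1, 2))
        lv = np.roll(lesion.voxels, shift, axis=(0, 1, 2))
        # roll is only a translation if nothing wraps
        if (pv.sum() != prostate.voxels.sum()
                or not _no_wrap(prostate.voxels, shift)):
            pytest.skip("phantom touches the boundary")
        p2 = SegmentationVolume(pv, prostate.spacing_mm)
        l2 = SegmentationVolume(lv, lesion.spacing_mm)
        cap2 = G.extract_capsule_surface(p2)
        for d in (1.0, 4.0):
            assert G.contact_surface_area(l2, cap2, d) == pytest.approx(
                G.contact_surface_area(lesion, cap, d))
        assert G.tumor_contact_length(l2, cap2, 1.0) == pytest.approx(
            G.tumor_contact_length(lesion, cap, 1.0))

    def test_empty_contact_consistency(self, rng):
        # lateral-contact phantoms: axial TCL and TCSA vanish together
        hits = 0
        for _ in range(10):
            prostate, lesion = random_phantom_pair(rng, max_grid=28)
            cap = G.extract_capsule_surface(prostate)
            tcl = G.tumor_contact_length(lesion, cap, 1.0)
            tcsa = G.contact_surface_area(lesion, cap, 1.0)
            assert (tcl == 0) == (tcsa == 0)
            hits += tcsa > 0
        assert hits > 0  # the family must actually exercise contact


def _no_wrap(mask, shift):
    idx = np.argwhere(mask)
    hi = idx.max(axis=0) + np.asarray(shift)
    return np.all(hi < mask.shape) and np.all(idx.min(axis=0) + shift >= 0)
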