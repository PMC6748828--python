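"""Morphometric statistics scored against generator ground truth."""

import numpy as np
import pytest
from wallmech import morphometrics as mo
from wallmech import synthetic as syn


class TestNematicAnisotropy:
    def test_constant_image_is_degenerate_zero(self):
        sc = mo.nematic_orientation_anisotropy(np.full((64, 64), 3.0))
        assert sc.anisotropy == 0.0 and sc.angle == 0.0 and sc.degenerate

    @pytest.mark.parametrize("angle", [0.0, 17.0, 30.0, 45.0, 75.0])
    def test_parallel_texture_recovers_angle_and_high_anisotropy(self, angle):
        img, truth = syn.make_fibril_texture(angle, coherence=1.0,
                                             noise_sd=0.0, seed=1)
        sc = mo.nematic_orientation_anisotropy(img)
        err = (sc.angle - truth.angle + 90.0) % 180.0 - 90.0
        assert abs(err) <= 2.0
        assert sc.anisotropy > 0.9

    def test_isotropic_texture_has_near_zero_anisotropy(self):
        img, _ = syn.make_fibril_texture(0.0, coherence=0.0, seed=2)
        assert mo.nematic_orientation_anisotropy(img).anisotropy < 0.05

    def test_anisotropy_monotone_in_coherence(self):
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        scores = []
        for c in levels:
            img, _ = syn.make_fibril_texture(30.0, c, noise_sd=0.05, seed=3)
            scores.append(mo.nematic_orientation_anisotropy(img).anisotropy)
        assert np.all(np.diff(scores) > 0)     # strictly increasing

    def test_rotation_equivariance(self):
        from skimage.transform import rotate
        img, _ = syn.make_fibril_texture(10.0, 1.0, seed=4, size=160)
        base = mo.nematic_orientation_anisotropy(img).angle
        for phi in (20.0, 45.0):
            rot = rotate(img, -phi, mode="reflect")   # ccw in xy convention
            inner = np.zeros(rot.shape, dtype=bool)
            inner[40:-40, 40:-40] = True              # avoid border artefacts
            got = mo.nematic_orientation_anisotropy(rot, roi=inner).angle
            err = (got - (base + phi) + 90.0) % 180.0 - 90.0
            assert abs(err) <= 3.0

    def test_intensity_scale_invariance(self):
        img, _ = syn.make_fibril_texture(30.0, 0.6, seed=5)
        a = mo.nematic_orientation_anisotropy(img)
        b = mo.nematic_orientation_anisotropy(7.3 * img)
        assert a.anisotropy == pytest.approx(b.anisotropy, rel=1e-9)
        assert a.angle == pytest.approx(b.angle, abs=1e-9)

    def test_polygon_roi_and_min_pixels(self):
        img, _ = syn.make_fibril_texture(30.0, 1.0, seed=6)
        poly = np.array([[10, 10], [100, 10], [100, 100], [10, 100]])
        sc = mo.nematic_orientation_anisotropy(img, roi=poly)
        assert sc.anisotropy > 0.9
        tiny = np.array([[1, 1], [4, 1], [4, 4], [1, 4]])
        with pytest.raises(ValueError):
            mo.nematic_orientation_anisotropy(img, roi=tiny)


class TestNormalizedAnisotropy:
    def test_equal_extremes_give_zero(self):
        assert mo.normalized_cell_anisotropy(0.25, 0.25) == 0.0

    def test_zero_minimum_gives_one(self):
        assert mo.normalized_cell_anisotropy(0.3, 0.0) == 1.0

    def test_intermediate_value(self):
        assert mo.normalized_cell_anisotropy(0.3, 0.1) == pytest.approx(0.5)

    def test_undefined_and_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            mo.normalized_cell_anisotropy(0.0, 0.0)
        with pytest.raises(ValueError):
            mo.normalized_cell_anisotropy(0.1, 0.2)   # a_max < a_min


class TestHysteresisFilter:
    def test_all_zero_image_gives_empty_mask(self):
        assert not mo.hysteresis_filter(np.zeros((8, 16, 16))).any()

    def test_bright_blob_recovered_exactly(self):
        rng = np.random.default_rng(0)
        img = np.zeros((4, 32, 32))
        img[1:3, 10:20, 10:20] = 1.0          # blob with a bright core
        img[2, 14:16, 14:16] = 5.0
        mask = mo.hysteresis_filter(img, low=0.5, high=4.0)
        assert np.array_equal(mask, img >= 0.5)

    def test_dim_blob_below_high_gives_empty_mask(self):
        img = np.zeros((2, 16, 16))
        img[0, 4:8, 4:8] = 1.0
        assert not mo.hysteresis_filter(img, low=0.5, high=2.0).any()

    def test_mask_subset_of_low_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.random((4, 32, 32)) ** 3
        mask = mo.hysteresis_filter(img)
        assert np.all(img[mask] >= img.mean())

    def test_inverted_thresholds_raise(self):
        with pytest.raises(ValueError):
            mo.hysteresis_filter(np.ones((4, 4)), low=2.0, high=1.0)


class TestManders:
    def test_identical_channels_give_unity(self):
        rng = np.random.default_rng(0)
        a = rng.random((32, 32))
        rep = mo.manders_edge_colocalisation(a, a, np.ones_like(a, bool))
        assert rep.M1 == 1.0 and rep.M2 == 1.0 and not rep.excluded

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[:10] = 1.0
        b[10:] = 1.0
        rep = mo.manders_edge_colocalisation(a, b, np.ones_like(a, bool))
        assert rep.M1 == 0.0 and rep.M2 == 0.0 and not rep.excluded

    def test_low_occupancy_channel_is_excluded(self):
        a, b, _ = syn.make_colocalised_pair(1.0, occupancy_a=0.05,
                                            occupancy_b=0.5, seed=1)
        rep = mo.manders_edge_colocalisation(a, b, np.ones_like(a, bool))
        assert rep.excluded

    def test_controlled_overlap_matches_truth(self):
        a, b, truth = syn.make_colocalised_pair(0.5, 0.3, 0.3, seed=2)
        rep = mo.manders_edge_colocalisation(a, b, np.ones_like(a, bool))
        assert rep.M1 == pytest.approx(truth.M1, abs=0.02)
        assert rep.M2 == pytest.approx(truth.M2, abs=0.02)

    def test_agrees_with_reference_implementation(self):
        # independent cross-check against scikit-image's Manders coefficient
        from skimage.measure import manders_coloc_coeff
        a, b, _ = syn.make_colocalised_pair(0.37, 0.4, 0.25, seed=3)
        rep = mo.manders_edge_colocalisation(a, b, np.ones_like(a, bool))
        assert rep.M1 == pytest.approx(
            manders_coloc_coeff(a, b > 0), abs=1e-12)
        assert rep.M2 == pytest.approx(
            manders_coloc_coeff(b, a > 0), abs=1e-12)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            mo.manders_edge_colocalisation(np.ones((4, 4)), np.ones((4, 4)),
                                           np.zeros((4, 4), bool))


class TestRootDiameter:
    def test_parallel_lines_give_exact_distance(self):
        x = np.arange(0, 300.0)
        a = np.column_stack([x, np.full_like(x, 25.0)])
        b = np.column_stack([x, np.full_like(x, -25.0)])
        assert mo.mean_root_diameter(a, b, 1.0, 100.0) == pytest.approx(50.0)

    def test_tapered_outline_matches_analytic_mean_within_1pct(self):
        ta, tb, truth = syn.make_root_outline(50.0, 100.0, 0.0, 500.0, 1.0)
        for excl in (0.0, 100.0):
            est = mo.mean_root_diameter(ta, tb, 1.0, excl)
            assert est == pytest.approx(
                truth.expected_mean_diameter(excl), rel=0.01)

    def test_tip_exclusion_increases_mean_on_tapering_root(self):
        ta, tb, _ = syn.make_root_outline(50.0, 100.0, 0.0, 500.0, 1.0)
        assert mo.mean_root_diameter(ta, tb, 1.0, 100.0) > \
            mo.mean_root_diameter(ta, tb, 1.0, 0.0)

    def test_unbiased_on_noiseless_parallel_root_to_subpixel(self):
        ta, tb, truth = syn.make_root_outline(40.0, 0.0, 0.0, 400.0, 1.0)
        est = mo.mean_root_diameter(ta, tb, 1.0, 50.0)
        assert abs(est - 40.0) < 1.0          # < 1 pixel

    def test_pixel_size_scaling(self):
        ta, tb, _ = syn.make_root_outline(50.0, 100.0, 0.0, 500.0,
                                          pixel_size=0.5)
        est = mo.mean_root_diameter(ta, tb, 0.5, 100.0)
        assert est == pytest.approx(50.0, rel=0.02)

    def test_trace_shorter_than_exclusion_raises(self):
        ta, tb, _ = syn.make_root_outline(50.0, 10.0, 0.0, 50.0, 1.0)
        with pytest.raises(ValueError):
            mo.mean_root_diameter(ta, tb, 1.0, 80.0)


class TestGrowthDecomposition:
    def test_identity_growth_is_meristematic_unity(self):
        m0, m1, _ = syn.make_cell_timepair(scales=(1.0, 1.0, 1.0))
        rep = mo.growth_decomposition(m0, m1)
        assert rep.volume_ratio == pytest.approx(1.0)
        assert rep.zone == "meristematic"

    def test_pure_longitudinal_doubling(self):
        m0, m1, truth = syn.make_cell_timepair(scales=(2.0, 1.0, 1.0))
        rep = mo.growth_decomposition(m0, m1)
        assert rep.volume_ratio == pytest.approx(2.0)
        assert rep.longitudinal_ratio == pytest.approx(2.0)
        assert rep.radial_ratio == pytest.approx(1.0)
        assert rep.circumferential_ratio == pytest.approx(1.0)
        assert rep.zone == "elongation" == truth.zone

    def test_isotropic_growth_cubes_the_volume(self):
        m0, m1, _ = syn.make_cell_timepair(scales=(1.2, 1.2, 1.2))
        rep = mo.growth_decomposition(m0, m1)
        assert rep.volume_ratio == pytest.approx(1.728)
        assert rep.zone == "elongation"

    def test_threshold_classifies_slow_growth_as_meristematic(self):
        m0, m1, truth = syn.make_cell_timepair(scales=(1.1, 1.05, 1.05))
        rep = mo.growth_decomposition(m0, m1)
        assert rep.volume_ratio == pytest.approx(1.1 * 1.05 * 1.05)
        assert rep.zone == "meristematic" == truth.zone

    def test_exact_on_general_affine_growth(self):
        m0, m1, truth = syn.make_cell_timepair(scales=(1.7, 0.9, 1.25))
        rep = mo.growth_decomposition(m0, m1)
        for f in ("volume_ratio", "longitudinal_ratio", "radial_ratio",
                  "circumferential_ratio"):
            assert getattr(rep, f) == pytest.approx(getattr(truth, f))

    def test_rotated_organ_frame(self):
        m0, m1, _ = syn.make_cell_timepair(scales=(2.0, 1.0, 1.0))
        frame = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        rep = mo.growth_decomposition(m0, m1, frame=frame)
        assert rep.longitudinal_ratio == pytest.approx(1.0)
        assert rep.radial_ratio == pytest.approx(2.0)

    def test_non_watertight_mesh_raises(self):
        import trimesh
        m0, m1, _ = syn.make_cell_timepair()
        broken = trimesh.Trimesh(vertices=m1.vertices,
                                 faces=m1.faces[:-2], process=False)
        with pytest.raises(ValueError):
            mo.growth_decomposition(m0, broken)


class TestEdgeEnrichment:
    def test_uniform_intensity_gives_unity_everywhere(self):
        vol, mask, edges, _ = syn.make_edge_intensity_cell(
            edge_ratios={"longitudinal": 1.0, "transverse": 1.0},
            background=1.0)
        vol[:] = 1.0
        rep = mo.edge_enrichment(vol, mask, edges, voxel_size=0.25)
        assert np.allclose(rep.relative_intensity, 1.0)

    def test_two_to_one_ratio_recovered(self):
        vol, mask, edges, truth = syn.make_edge_intensity_cell(
            edge_ratios={"longitudinal": 2.0, "transverse": 1.0},
            noise_sd=0.05, seed=1)
        rep = mo.edge_enrichment(vol, mask, edges, voxel_size=0.25)
        assert rep.class_mean("longitudinal") > 1.0 > \
            rep.class_mean("transverse")
        ratio = rep.class_mean("longitudinal") / rep.class_mean("transverse")
        assert ratio == pytest.approx(2.0, rel=0.10)
        assert np.allclose(rep.relative_intensity, truth.relative_intensity,
                           rtol=0.10)

    def test_voxel_weighted_mean_is_unity(self):
        vol, mask, edges, _ = syn.make_edge_intensity_cell(seed=2,
                                                           noise_sd=0.1)
        rep = mo.edge_enrichment(vol, mask, edges, voxel_size=0.25)
        w = rep.voxel_counts
        assert (rep.relative_intensity * w).sum() / w.sum() == \
            pytest.approx(1.0, rel=1e-12)

    def test_joint_translation_invariance(self):
        vol, mask, edges, _ = syn.make_edge_intensity_cell(seed=3)
        rep0 = mo.edge_enrichment(vol, mask, edges, voxel_size=0.25)
        # shift volume, mask and edge lines by two voxels along x
        vol2 = np.roll(vol, 2, axis=0)
        mask2 = np.roll(mask, 2, axis=0)
        shift = np.array([2 * 0.25, 0, 0])
        edges2 = [mo.EdgeSegment(e.p0 + shift, e.p1 + shift, e.edge_class)
                  for e in edges]
        rep2 = mo.edge_enrichment(vol2, mask2, edges2, voxel_size=0.25)
        assert np.allclose(rep0.relative_intensity, rep2.relative_intensity,
                           rtol=1e-9)

    def test_intensity_scale_invariance(self):
        vol, mask, edges, _ = syn.make_edge_intensity_cell(seed=4)
        rep1 = mo.edge_enrichment(vol, mask, edges, voxel_size=0.25)
        rep2 = mo.edge_enrichment(5.0 * vol, mask, edges, voxel_size=0.25)
        assert np.allclose(rep1.relative_intensity, rep2.relative_intensity)

    def test_edge_lengths_reported_per_class(self):
        _, _, edges, _ = syn.make_edge_intensity_cell(
            cell_dims=(10.0, 6.0, 6.0))
        longs = [e.length for e in edges if e.edge_class == "longitudinal"]
        assert np.allclose(longs, 10.0)

    def test_empty_band_raises(self):
        vol, mask, edges, _ = syn.make_edge_intensity_cell(seed=5)
        far = [mo.EdgeSegment(np.array([50.0, 50, 50]),
                              np.array([60.0, 50, 50]), "longitudinal")]
        with pytest.raises(ValueError):
            mo.edge_enrichment(vol, mask, far, voxel_size=0.25)
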