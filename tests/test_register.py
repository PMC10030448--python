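"""Three-stage registration: affine recovery, distance preservation,
restricted demons contracts. Tests run on coarse grids so each stage
finishes in seconds; the clinical defaults are exercised in the
acceptance suite."""

import numpy as np
import pytest

from corseg import (AffineParams, DemonsParams, RegistrationError, SpatialTransform,
                    StructureGuidedParams, affine_register, demons_register, dsc,
                    register_atlas, resample_mask, signed_distance,
                    structure_guided_deformable)
from corseg.phantom import AtlasCase
from conftest import ellipsoid, make_grid, sphere
from scipy.ndimage import map_coordinates


@pytest.fixture(scope="module")
def g2mm():
    return make_grid((64, 64, 64), (2.0, 2.0, 2.0))


AFFINE_FAST = AffineParams(shrink_factors=(8, 4))


class TestAffine:
    def test_self_registration_is_identity(self, g2mm):
        m = sphere(g2mm, (64, 64, 64), 30.0)
        t = affine_register(m, m, AFFINE_FAST)
        assert t.max_mask_displacement_mm(m) < max(g2mm.spacing)

    def test_translation_recovered_within_1mm(self, g2mm):
        atlas = sphere(g2mm, (60, 64, 64), 30.0)
        target = sphere(g2mm, (70, 64, 64), 30.0)  # atlas translated +10 mm in x
        t = affine_register(atlas, target, AFFINE_FAST)
        mapped = t.transform_points(np.array([70.0, 64.0, 64.0]))
        assert np.linalg.norm(mapped - [60.0, 64.0, 64.0]) < 1.0

    def test_isotropic_scale_recovered(self, g2mm):
        atlas = sphere(g2mm, (64, 64, 64), 25.0)
        target = sphere(g2mm, (64, 64, 64), 30.0)  # scaled x1.2 about centroid
        t = affine_register(atlas, target, AFFINE_FAST)
        scale = 1.0 / np.linalg.det(t.affine_matrix) ** (1 / 3)
        assert scale == pytest.approx(1.2, abs=0.05)

    def test_empty_mask_rejected(self, g2mm):
        from corseg import BinaryMask

        m = sphere(g2mm, (64, 64, 64), 20.0)
        empty = BinaryMask.from_array(np.zeros(g2mm.shape), g2mm)
        with pytest.raises(RegistrationError):
            affine_register(empty, m)


class TestStructureGuided:
    def test_identical_masks_give_near_zero_field(self, g2mm):
        m = sphere(g2mm, (64, 64, 64), 30.0)
        t = structure_guided_deformable(m, m)
        assert t.max_mask_displacement_mm(m) < max(g2mm.spacing)

    def test_sphere_to_ellipsoid_boundary_coregistration(self, g2mm):
        atlas = sphere(g2mm, (64, 64, 64), 30.0)
        target = ellipsoid(g2mm, (64, 64, 64), (36, 27, 30))
        t = structure_guided_deformable(atlas, target)
        warped = resample_mask(atlas, target.grid, t.sitk_transform)
        assert dsc(warped, target) >= 0.98

    def test_normalised_depth_preserved(self, g2mm):
        atlas = sphere(g2mm, (64, 64, 64), 30.0)
        target = ellipsoid(g2mm, (64, 64, 64), (36, 27, 30))
        t = structure_guided_deformable(atlas, target)
        sd_target = signed_distance(target, normalise=True)
        sd_atlas = signed_distance(atlas, normalise=True)
        for level in (-0.25, -0.5, -0.75):
            idx = np.argwhere(np.abs(sd_target.values - level) < 0.02)[::5]
            pts = target.grid.index_to_world(idx)
            mapped = t.transform_points(pts)
            ci = atlas.grid.world_to_index(mapped).T
            depths = map_coordinates(sd_atlas.values, ci, order=1)
            assert np.abs(depths - level).max() <= 0.1

    def test_init_mapping_atlas_outside_target_rejected(self, g2mm):
        atlas = sphere(g2mm, (64, 64, 64), 20.0)
        target = sphere(g2mm, (64, 64, 64), 20.0)
        away = SpatialTransform.from_affine(np.eye(3), (1000.0, 0.0, 0.0))
        with pytest.raises(RegistrationError, match="outside"):
            structure_guided_deformable(atlas, target, init=away)


DEMONS_FAST = DemonsParams(level_voxel_sizes_mm=(6.0, 4.0), iterations_per_level=(25, 15))


class TestDemons:
    def test_identical_images_give_near_zero_field(self, small_phantom):
        img, ss = small_phantom
        t = demons_register(img, img, ss["WH"], None, DEMONS_FAST)
        wh = ss["WH"]
        pts = wh.grid.index_to_world(np.argwhere(wh.values > 0)[::19])
        disp = np.linalg.norm(t.transform_points(pts) - pts, axis=1)
        assert disp.mean() < 0.5

    def test_update_identically_zero_outside_roi(self, small_phantom):
        img, ss = small_phantom
        from corseg import morphology

        t = demons_register(img, img, ss["WH"], None, DEMONS_FAST)
        roi = morphology(ss["WH"], "dilate", DEMONS_FAST.roi_margin_mm)
        outside_idx = np.argwhere(roi.values == 0)[::97]
        pts = roi.grid.index_to_world(outside_idx)
        assert np.allclose(t.transform_points(pts), pts, atol=1e-9)

    def test_perturbation_outside_roi_does_not_change_field_inside(self, small_phantom):
        img, ss = small_phantom
        t_ref = demons_register(img, img, ss["WH"], None, DEMONS_FAST)
        perturbed = img.values.copy()
        perturbed[:6, :6, :6] += 500.0  # far corner, outside the heart ROI
        img_p = img.with_values(perturbed)
        t_p = demons_register(img_p, img_p, ss["WH"], None, DEMONS_FAST)
        wh = ss["WH"]
        pts = wh.grid.index_to_world(np.argwhere(wh.values > 0)[::29])
        diff = np.linalg.norm(t_ref.transform_points(pts) - t_p.transform_points(pts), axis=1)
        assert diff.max() < 0.1

    def test_jacobian_positive_in_roi(self, small_phantom, small_cohort):
        img, ss = small_phantom
        target = small_cohort[0]
        t = demons_register(img, target.image, target.structures["WH"], None, DEMONS_FAST)
        from corseg import morphology

        roi = morphology(target.structures["WH"], "dilate", DEMONS_FAST.roi_margin_mm)
        jac = t.jacobian_determinant(img)
        interior = morphology(roi, "erode", 4.0).values > 0
        assert jac.values[interior].min() > 0


class TestRegisterAtlas:
    def test_self_registration_preserves_structures(self, small_phantom, fast_config):
        img, ss = small_phantom
        atlas = AtlasCase("self", img, ss)
        _, warped = register_atlas(atlas, img, ss["WH"], fast_config.registration)
        for n in ("LA", "LV", "RA", "RV", "AA", "PA", "SVC", "WH"):
            assert dsc(warped[n], ss[n]) >= 0.95

    def test_composite_equals_sequential_stage_application(self, g2mm):
        atlas = sphere(g2mm, (60, 64, 64), 28.0)
        target = ellipsoid(g2mm, (68, 64, 64), (32, 26, 28))
        t_aff = affine_register(atlas, target, AFFINE_FAST)
        t_sg = structure_guided_deformable(atlas, target, t_aff)
        # t_sg = compose([field, t_aff]): applying it must equal applying
        # the field then the affine
        field, aff = t_sg.components
        pts = target.grid.index_to_world(np.argwhere(target.values > 0)[::40])
        seq = aff.transform_points(field.transform_points(pts))
        assert np.abs(t_sg.transform_points(pts) - seq).max() < 1e-3

    def test_monotone_metric_improvement_across_stages(self, g2mm):
        atlas = sphere(g2mm, (60, 64, 64), 28.0)
        target = ellipsoid(g2mm, (70, 66, 64), (33, 26, 29))
        before = dsc(atlas, target)
        t_aff = affine_register(atlas, target, AFFINE_FAST)
        after_aff = dsc(resample_mask(atlas, target.grid, t_aff.sitk_transform), target)
        t_sg = structure_guided_deformable(atlas, target, t_aff)
        after_sg = dsc(resample_mask(atlas, target.grid, t_sg.sitk_transform), target)
        assert before < after_aff < after_sg
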