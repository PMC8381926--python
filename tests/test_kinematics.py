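import numpy as np
import pytest

from ctmotion import AnalysisConfig, RigidTransform, run_ctma
from ctmotion.kinematics import (
    MigrationResult,
    center_of_mass,
    decompose_6dof,
    recompose,
    relative_motion,
    reorient,
)
from ctmotion.segmentation import EmptyMaskError
from ctmotion.volume_io import CTVolume
from tests.test_registration import random_transform


class TestRelativeMotion:
    def test_equal_transforms_give_identity(self, rng):
        t = random_transform(rng)
        rel = relative_motion(t, t)
        assert rel.isclose(RigidTransform.identity(), atol_mm=1e-9, atol_deg=1e-9)

    def test_bone_identity_passes_implant_through(self):
        implant = RigidTransform(np.eye(3), [0.2, 0.0, 0.0])
        rel = relative_motion(RigidTransform.identity(), implant)
        assert np.allclose(rel.translation, [0.2, 0.0, 0.0], atol=1e-12)

    def test_pointwise_composition_oracle(self, rng):
        # relative motion must act on points exactly like undoing the bone
        # motion after applying the implant motion
        bone = random_transform(rng)
        implant = random_transform(rng)
        rel = relative_motion(bone, implant)
        pts = rng.normal(size=(100, 3)) * 20
        expected = bone.inverse().apply(implant.apply(pts))
        assert np.abs(rel.apply(pts) - expected).max() < 1e-9


class TestDecompose6DOF:
    def test_identity_motion_is_zero(self):
        res = decompose_6dof(RigidTransform.identity(), [10.0, 5.0, 2.0])
        assert np.allclose(res.dof, 0.0, atol=1e-12)

    def test_pure_rotation_about_com_origin(self):
        motion = RigidTransform.from_euler([0.0, 0.0, 5.0])
        res = decompose_6dof(motion, [0.0, 0.0, 0.0])
        assert np.allclose(res.translations_mm, 0.0, atol=1e-12)
        assert np.allclose(res.rotations_deg, [0.0, 0.0, 5.0], atol=1e-9)

    def test_translation_is_com_displacement(self, rng):
        motion = random_transform(rng)
        com = rng.normal(size=3) * 30
        res = decompose_6dof(motion, com)
        assert np.allclose(res.translations_mm, motion.apply(com) - com, atol=1e-12)

    def test_500_random_round_trips(self, rng):
        for _ in range(500):
            motion = random_transform(rng, max_t=20.0, max_r=170.0)
            com = rng.normal(size=3) * 40
            res = decompose_6dof(motion, com)
            back = recompose(res)
            delta = back.inverse() @ motion
            assert np.linalg.norm(delta.translation) < 1e-9
            assert delta.rotation_angle_deg < 1e-9

    def test_gimbal_proximity_flagged_with_alternative(self):
        motion = RigidTransform.from_euler([10.0, 89.95, 20.0])
        res = decompose_6dof(motion, np.zeros(3))
        assert res.gimbal_warning
        assert res.alt_euler_order is not None
        # the alternate sequence still recomposes to the same rotation
        from scipy.spatial.transform import Rotation
        alt = Rotation.from_euler(res.alt_euler_order, res.alt_rotations_deg,
                                  degrees=True).as_matrix()
        assert np.abs(alt - motion.rotation).max() < 1e-9

    def test_rotations_within_principal_range(self, rng):
        for _ in range(50):
            res = decompose_6dof(random_transform(rng, max_r=179.0),
                                 rng.normal(size=3))
            assert np.all(res.rotations_deg > -180.0)
            assert np.all(res.rotations_deg <= 180.0)


class TestCenterOfMass:
    def test_single_voxel(self):
        vol = CTVolume(np.zeros((5, 5, 5)), [1.0, 1.0, 1.0], origin=[0.0, 0.0, 0.0])
        mask = np.zeros((5, 5, 5), bool)
        mask[1, 2, 3] = True
        assert np.allclose(center_of_mass(mask, vol), [1.0, 2.0, 3.0])

    def test_symmetric_hemisphere_on_axis(self):
        # mask symmetric under x -> -x and y -> -y about the grid centre
        n = 41
        vol = CTVolume(np.zeros((n, n, n)), [0.5] * 3)
        idx = np.indices((n, n, n)).reshape(3, -1).T - (n - 1) / 2
        r = np.linalg.norm(idx, axis=1)
        mask = ((r <= 15) & (r >= 10) & (idx[:, 2] >= 0)).reshape(n, n, n)
        com = center_of_mass(mask, vol)
        centre = vol.index_to_world([(n - 1) / 2] * 3)
        assert abs(com[0] - centre[0]) < 1e-6
        assert abs(com[1] - centre[1]) < 1e-6
        assert com[2] > centre[2]

    def test_two_equal_blobs_midpoint(self):
        vol = CTVolume(np.zeros((10, 10, 10)), [1.0] * 3)
        mask = np.zeros((10, 10, 10), bool)
        mask[1, 1, 1] = True
        mask[7, 5, 3] = True
        assert np.allclose(center_of_mass(mask, vol), [4.0, 3.0, 2.0])

    def test_empty_mask_errors(self):
        vol = CTVolume(np.zeros((4, 4, 4)), [1.0] * 3)
        with pytest.raises(EmptyMaskError):
            center_of_mass(np.zeros((4, 4, 4), bool), vol)


class TestReorient:
    def make_result(self, rng):
        motion = random_transform(rng, max_t=2.0, max_r=5.0)
        com = rng.normal(size=3) * 20
        return decompose_6dof(motion, com)

    def test_identity_basis_is_identity_operation(self, rng):
        res = self.make_result(rng)
        out = reorient(res, np.eye(3), (1, 1, 1))
        assert out.frame == "anatomical"
        assert np.allclose(out.dof, res.dof, atol=1e-9)

    def test_axis_swap_permutes_translation(self):
        # proper rotation taking x -> y
        basis = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        motion = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        res = decompose_6dof(motion, np.zeros(3))
        out = reorient(res, basis)
        assert np.allclose(out.translations_mm, [0.0, 1.0, 0.0], atol=1e-12)

    def test_sign_convention_flips_rotations(self, rng):
        res = self.make_result(rng)
        out = reorient(res, np.eye(3), (1, -1, 1))
        assert np.allclose(out.rotations_deg * [1, -1, 1], res.rotations_deg,
                           atol=1e-9)

    def test_commuting_diagram_against_raw_point_clouds(self, rng):
        # reorienting the result must equal transforming raw points into
        # the new basis first and re-deriving the 6 DOF there
        from ctmotion.registration import kabsch_fit

        motion = random_transform(rng, max_t=2.0, max_r=5.0)
        com = rng.normal(size=3) * 10
        basis = random_transform(rng).rotation
        pts = rng.normal(size=(20, 3)) * 15
        res = decompose_6dof(motion, com)
        out = reorient(res, basis)

        moved = motion.apply(pts)
        fitted, _ = kabsch_fit(pts @ basis.T, moved @ basis.T)
        direct = decompose_6dof(fitted, basis @ com)
        assert np.abs(out.dof - direct.dof).max() < 1e-9

    def test_non_orthonormal_basis_rejected(self, rng):
        res = self.make_result(rng)
        with pytest.raises(ValueError):
            reorient(res, np.eye(3) * 2.0)


class TestRunCtma:
    def test_zero_motion_recovery(self, static_pair):
        vol1, vol2, _ = static_pair
        res = run_ctma(vol1, vol2, AnalysisConfig())
        assert np.abs(res.translations_mm).max() < 0.05
        assert np.abs(res.rotations_deg).max() < 0.1

    def test_same_volume_twice_is_zero(self, clean_pair):
        vol1, _, _ = clean_pair
        for mode in ("beads", "surface"):
            res = run_ctma(vol1, vol1, AnalysisConfig(registration_mode=mode))
            assert np.abs(res.translations_mm).max() < 1e-9
            assert np.abs(res.rotations_deg).max() < 1e-9

    @pytest.mark.parametrize("mode", ["beads", "surface"])
    def test_known_migration_recovery(self, noisy_pair, mode):
        vol1, vol2, gt = noisy_pair
        res = run_ctma(vol1, vol2, AnalysisConfig(registration_mode=mode))
        truth = decompose_6dof(gt.migration, res.center_of_mass_mm)
        err = np.abs(res.dof - truth.dof)
        assert err[:3].max() < 0.1
        assert err[3:].max() < 0.3
        assert res.mode == mode and res.frame == "dicom"
        assert set(res.quality) == {"bone", "implant"}

    def test_modes_agree_on_clean_phantom(self, clean_pair):
        vol1, vol2, _ = clean_pair
        a = run_ctma(vol1, vol2, AnalysisConfig(registration_mode="beads"))
        b = run_ctma(vol1, vol2, AnalysisConfig(registration_mode="surface"))
        assert np.abs(a.translations_mm - b.translations_mm).max() < 0.1
        assert np.abs(a.rotations_deg - b.rotations_deg).max() < 0.3

    def test_anatomical_frame_output(self, clean_pair):
        vol1, vol2, _ = clean_pair
        res = run_ctma(vol1, vol2,
                       AnalysisConfig(target_frame="anatomical"))
        assert res.frame == "anatomical"

    def test_global_equivariance_of_registration_algebra(self, rng):
        # an extra global rigid motion applied to every exam-2 structure is
        # absorbed by the bone registration and cancels exactly
        from ctmotion.registration import kabsch_fit

        bone1 = rng.normal(size=(6, 3)) * 15
        impl1 = rng.normal(size=(4, 3)) * 5
        repo = random_transform(rng, max_t=5.0, max_r=5.0)
        mig = random_transform(rng, max_t=1.0, max_r=2.0)
        com = rng.normal(size=3) * 10
        g = random_transform(rng, max_t=50.0, max_r=90.0)

        def analyse(extra):
            bone_t, _ = kabsch_fit(bone1, extra.apply(repo.apply(bone1)))
            impl_t, _ = kabsch_fit(impl1, extra.apply((repo @ mig).apply(impl1)))
            return decompose_6dof(relative_motion(bone_t, impl_t), com)

        base = analyse(RigidTransform.identity())
        moved = analyse(g)
        assert np.abs(base.dof - moved.dof).max() < 1e-6

    def test_pipeline_error_names_stage(self, clean_pair):
        from ctmotion.kinematics import PipelineError

        vol1, _, _ = clean_pair
        empty = CTVolume(np.full_like(np.asarray(vol1.data), 40.0), vol1.spacing)
        with pytest.raises(PipelineError, match="segmentation"):
            run_ctma(vol1, empty, AnalysisConfig())


class TestMigrationResult:
    def test_rotation_range_enforced(self):
        with pytest.raises(ValueError, match="rotations"):
            MigrationResult(np.zeros(3), [0.0, 200.0, 0.0], np.zeros(3), "dicom")

    def test_frame_label_enforced(self):
        with pytest.raises(ValueError, match="frame"):
            MigrationResult(np.zeros(3), np.zeros(3), np.zeros(3), "scanner")
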