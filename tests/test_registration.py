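import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ctmotion.registration import (
    DegenerateConfigurationError,
    MatchingError,
    RegistrationQuality,
    RigidTransform,
    coarse_align,
    condition_number,
    icp_register,
    kabsch_fit,
    match_beads,
    quality_gate,
)
from ctmotion.segmentation import BeadSet, PointCloud


def random_transform(rng, max_t=10.0, max_r=30.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_r, max_r)
    t = rng.uniform(-max_t, max_t, size=3)
    return RigidTransform.from_axis_angle(axis, angle, t)


# ---------------------------------------------------------------------------
# RigidTransform


class TestRigidTransform:
    def test_identity(self):
        t = RigidTransform.identity()
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(t.apply(p), p)

    def test_rejects_reflection(self):
        with pytest.raises(ValueError, match="proper rotation"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_compose_inverse(self, rng):
        a = random_transform(rng)
        b = random_transform(rng)
        p = rng.normal(size=(50, 3))
        assert np.allclose((a @ b).apply(p), a.apply(b.apply(p)), atol=1e-10)
        assert np.allclose((a @ a.inverse()).rotation, np.eye(3), atol=1e-12)
        assert np.allclose((a @ a.inverse()).translation, 0.0, atol=1e-12)

    def test_rotation_angle(self):
        t = RigidTransform.from_axis_angle([0, 0, 1], 37.5)
        assert t.rotation_angle_deg == pytest.approx(37.5, abs=1e-9)

    def test_json_round_trip(self, tmp_path, rng):
        t = random_transform(rng)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = RigidTransform.from_json(path)
        assert t.isclose(back, atol_mm=1e-12, atol_deg=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_composition_stays_on_so3(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform.identity()
        for _ in range(20):
            t = t @ random_transform(rng)
        r = t.rotation
        assert np.abs(r.T @ r - np.eye(3)).max() < 1e-9
        assert abs(np.linalg.det(r) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# kabsch_fit


def brute_force_rigid_fit(source, target, coarse_deg=6.0, fine_deg=0.5):
    """Independent oracle: exhaustive Euler-grid search over rotations.

    Coarse pass over the full rotation space, then a local refinement grid
    at ``fine_deg`` resolution. Translation is eliminated in closed form
    (centroid alignment), so only the rotation is searched.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    a = src - src.mean(axis=0)
    b = tgt - tgt.mean(axis=0)

    def residual(mats):
        moved = np.einsum("kij,nj->kni", mats, a)
        return np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=2), axis=1))

    def grid(center, span, step):
        ax = [np.arange(c - s, c + s + 1e-9, step)
              for c, s in zip(center, span)]
        mesh = np.meshgrid(*ax, indexing="ij")
        angles = np.column_stack([m.ravel() for m in mesh])
        return angles

    angles = grid((0, 90, 0), (180, 90, 180), coarse_deg)
    mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
    coarse = mats[int(np.argmin(residual(mats)))]
    # refine in rotation-vector space about the coarse winner (Euler
    # coordinates degenerate near gimbal; rotvec perturbations do not)
    deltas = np.deg2rad(grid((0.0, 0.0, 0.0), (coarse_deg,) * 3, fine_deg))
    mats = Rotation.from_rotvec(deltas).as_matrix() @ coarse
    rot = mats[int(np.argmin(residual(mats)))]
    t = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    return RigidTransform(rot, t)


class TestKabsch:
    def test_identity_on_axes(self):
        pts = np.eye(3)
        transform, quality = kabsch_fit(pts, pts)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(transform.translation, 0.0, atol=1e-12)
        assert quality.mean_error_mm == pytest.approx(0.0, abs=1e-12)

    def test_rz90_closed_form(self):
        src = np.eye(3)
        rz90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        transform, quality = kabsch_fit(src, src @ rz90.T)
        assert np.allclose(transform.rotation, rz90, atol=1e-12)
        assert np.allclose(transform.translation, 0.0, atol=1e-12)
        assert quality.mean_error_mm < 1e-12

    def test_pure_translation(self):
        src = np.eye(3)
        transform, _ = kabsch_fit(src, src + np.array([1.0, 2.0, 3.0]))
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(transform.translation, [1.0, 2.0, 3.0], atol=1e-12)

    def test_recovers_random_transforms_exactly(self, rng):
        for _ in range(20):
            truth = random_transform(rng)
            src = rng.normal(size=(8, 3)) * 15
            transform, quality = kabsch_fit(src, truth.apply(src))
            assert transform.isclose(truth, atol_mm=1e-9, atol_deg=1e-9)
            assert quality.mean_error_mm < 1e-10

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(3):
            truth = random_transform(rng, max_t=5.0, max_r=60.0)
            src = rng.normal(size=(5, 3)) * 10
            tgt = truth.apply(src)
            fast, _ = kabsch_fit(src, tgt)
            slow = brute_force_rigid_fit(src, tgt)
            delta = fast.inverse() @ slow
            assert delta.rotation_angle_deg < 0.5  # grid resolution

    def test_collinear_raises_with_rank(self):
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateConfigurationError, match="rank"):
            kabsch_fit(line, line)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_fit(np.eye(3), np.zeros((4, 3)))

    def test_left_invariance(self, rng):
        src = rng.normal(size=(10, 3)) * 10
        truth = random_transform(rng)
        tgt = truth.apply(src)
        g = random_transform(rng)
        fitted, _ = kabsch_fit(src, tgt)
        fitted_g, _ = kabsch_fit(g.apply(src), g.apply(tgt))
        conjugated = g @ fitted @ g.inverse()
        assert fitted_g.isclose(conjugated, atol_mm=1e-9, atol_deg=1e-9)


# ---------------------------------------------------------------------------
# condition number and gates


class TestConditionNumber:
    def test_regular_tetrahedron_is_isotropic(self):
        # the centred second-moment tensor of a regular tetrahedron is a
        # multiple of the identity, so all singular values coincide
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        assert condition_number(pts) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_flagged_infinite(self):
        line = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        assert np.isinf(condition_number(line))

    def test_scale_invariance(self, rng):
        pts = rng.normal(size=(7, 3))
        assert condition_number(pts * 10) == pytest.approx(
            condition_number(pts), rel=1e-9)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(6, 3)) * 5
        g = random_transform(rng)
        assert condition_number(g.apply(pts)) == pytest.approx(
            condition_number(pts), rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(DegenerateConfigurationError):
            condition_number(np.zeros((2, 3)))


class TestQualityGate:
    def make(self, cn, me):
        return RegistrationQuality(mean_error_mm=me, condition_number=cn, n_points=6)

    def test_pass_within_limits(self):
        gate = quality_gate(self.make(50.0, 0.1))
        assert gate.passed and gate.reasons == ()

    def test_high_condition_number_fails(self):
        gate = quality_gate(self.make(150.0, 0.1))
        assert not gate.passed
        assert any("condition number" in r for r in gate.reasons)

    def test_high_mean_error_fails(self):
        gate = quality_gate(self.make(50.0, 0.35))
        assert not gate.passed
        assert any("mean error" in r for r in gate.reasons)

    def test_boundary_values_fail(self):
        # gate is strict: exactly at the limit counts as failed
        assert not quality_gate(self.make(100.0, 0.1)).passed
        assert not quality_gate(self.make(50.0, 0.30)).passed

    def test_infinite_condition_number_fails(self):
        assert not quality_gate(self.make(float("inf"), 0.0)).passed


# ---------------------------------------------------------------------------
# bead matching


def bead_set(points):
    return BeadSet(np.asarray(points, float), np.arange(len(points)))


class TestMatchBeads:
    def test_identity_pairing(self, rng):
        pts = rng.normal(size=(6, 3)) * 10
        corr = match_beads(bead_set(pts), bead_set(pts))
        assert corr.n_pairs == 6
        assert corr.unmatched_a == () and corr.unmatched_b == ()
        assert np.array_equal(corr.index_a, corr.index_b)

    def test_dropout_reported(self, rng):
        pts = rng.normal(size=(6, 3)) * 10
        corr = match_beads(bead_set(pts), bead_set(pts[:-1]))
        assert corr.n_pairs == 5
        assert corr.unmatched_a == (5,)

    def test_perfect_pairing_under_known_transform(self, rng):
        pts = rng.normal(size=(7, 3)) * 10
        truth = random_transform(rng)
        corr = match_beads(bead_set(pts), bead_set(truth.apply(pts)), init=truth)
        assert corr.n_pairs == 7
        assert np.array_equal(corr.index_a, corr.index_b)

    def test_triplet_fallback_without_init(self, rng):
        # motion large relative to bead spacing: naive mutual NN aliases,
        # the distance-consistency search must still find the truth
        pts = rng.normal(size=(6, 3)) * 8
        truth = random_transform(rng, max_t=15.0, max_r=40.0)
        corr = match_beads(bead_set(pts), bead_set(truth.apply(pts)))
        fitted, quality = kabsch_fit(pts[corr.index_a],
                                     truth.apply(pts)[corr.index_b])
        assert corr.n_pairs == 6
        assert fitted.isclose(truth, atol_mm=1e-9, atol_deg=1e-9)

    def test_too_few_beads(self):
        with pytest.raises(MatchingError):
            match_beads(bead_set(np.eye(3)[:2]), bead_set(np.eye(3)))


# ---------------------------------------------------------------------------
# ICP


class TestICP:
    def test_identity_case(self, rng):
        pts = rng.normal(size=(300, 3)) * 10
        transform, quality = icp_register(PointCloud(pts), PointCloud(pts))
        assert quality.iterations == 1
        assert quality.converged
        assert quality.mean_error_mm == pytest.approx(0.0, abs=1e-12)
        assert transform.isclose(RigidTransform.identity(), 1e-12, 1e-9)

    def test_equals_kabsch_on_matched_clouds(self, rng):
        # jittered grid: point spacing >> motion, so nearest neighbours are
        # the true correspondences and ICP must reproduce the direct fit
        base = np.stack(np.meshgrid(*[np.arange(0, 40, 8.0)] * 3,
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        pts = base + rng.uniform(-1.5, 1.5, size=base.shape)
        truth = random_transform(rng, max_t=0.5, max_r=1.0)
        tgt = truth.apply(pts)
        icp_t, _ = icp_register(PointCloud(pts), PointCloud(tgt), tol_mm=1e-9)
        kabsch_t, _ = kabsch_fit(pts, tgt)
        assert icp_t.isclose(kabsch_t, atol_mm=1e-6, atol_deg=1e-6)

    def test_recovers_transform_on_phantom_surface(self, clean_pair, config):
        from ctmotion.kinematics import _bone_surface_cloud

        vol1, _, _ = clean_pair
        cloud = _bone_surface_cloud(vol1, 600.0, 2200.0)
        truth = RigidTransform.from_euler([0.0, 0.0, 3.0], [2.0, 0.0, 0.0])
        moved = PointCloud(truth.apply(cloud.points))
        transform, quality = icp_register(cloud, moved, metric="plane", tol_mm=1e-6)
        delta = transform.inverse() @ truth
        assert np.linalg.norm(delta.translation) < 0.05
        assert delta.rotation_angle_deg < 0.05

    def test_final_rms_not_worse_than_initial(self, rng):
        src = rng.normal(size=(500, 3)) * 10
        truth = random_transform(rng, max_t=2.0, max_r=5.0)
        tgt = truth.apply(src) + rng.normal(scale=0.05, size=(500, 3))
        from scipy.spatial import cKDTree

        d0, _ = cKDTree(tgt).query(src)
        rms0 = float(np.sqrt(np.mean(d0**2)))
        _, quality = icp_register(PointCloud(src), PointCloud(tgt))
        assert quality.mean_error_mm <= rms0 + 1e-12

    def test_left_invariance_point_metric(self, rng):
        src = rng.normal(size=(400, 3)) * 10
        truth = random_transform(rng, max_t=1.0, max_r=2.0)
        tgt = truth.apply(src)
        g = random_transform(rng)
        t1, _ = icp_register(PointCloud(src), PointCloud(tgt), tol_mm=1e-10)
        t2, _ = icp_register(PointCloud(g.apply(src)), PointCloud(g.apply(tgt)),
                             tol_mm=1e-10)
        assert t2.isclose(g @ t1 @ g.inverse(), atol_mm=1e-9, atol_deg=1e-9)

    def test_unknown_metric(self, rng):
        pts = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="metric"):
            icp_register(PointCloud(pts), PointCloud(pts), metric="chamfer")


# ---------------------------------------------------------------------------
# coarse alignment


class TestCoarseAlign:
    def test_identity(self, rng):
        pts = rng.normal(size=(200, 3)) * np.array([10.0, 5.0, 2.0])
        t = coarse_align(PointCloud(pts), PointCloud(pts))
        assert t.isclose(RigidTransform.identity(), atol_mm=1e-6, atol_deg=1e-6)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(200, 3)) * np.array([10.0, 5.0, 2.0])
        shift = np.array([4.0, -2.0, 7.0])
        t = coarse_align(PointCloud(pts), PointCloud(pts + shift))
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(t.translation, shift, atol=1e-6)

    def test_isotropic_cloud_warns_and_centroid_aligns(self, rng):
        # points on a sphere: principal moments coincide
        pts = rng.normal(size=(2000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.warns(UserWarning, match="isotropic"):
            t = coarse_align(PointCloud(pts), PointCloud(pts + [1.0, 0.0, 0.0]))
        assert np.allclose(t.rotation, np.eye(3))

    def test_phantom_surface_capture(self, clean_pair):
        # bone surface under a 10 mm / 10 deg repositioning: the residual
        # after coarse alignment must be small enough for ICP capture
        from scipy.spatial import cKDTree

        from ctmotion.kinematics import _bone_surface_cloud

        vol1, _, _ = clean_pair
        c1 = _bone_surface_cloud(vol1, 600.0, 2200.0)
        motion = RigidTransform.from_axis_angle([1.0, 2.0, 0.5], 10.0,
                                                [6.0, -5.0, 6.0])
        c2 = PointCloud(motion.apply(c1.points))
        init = coarse_align(c1, c2)
        d, _ = cKDTree(c2.points).query(init.apply(c1.points))
        assert float(np.sqrt(np.mean(d**2))) < 2.0
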