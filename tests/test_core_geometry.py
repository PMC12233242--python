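"""Rigid-body primitives: Kabsch alignment, Rodrigues, quaternions, SLERP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from dentalign.core_geometry import (
    RigidTransform,
    kabsch_align,
    quat_slerp,
    quat_to_rotmat,
    read_transform_text,
    rodrigues_rotation,
    rotmat_to_quat,
    transform_points,
    write_transform_text,
)
from .conftest import random_rotation


class TestKabsch:
    def test_identity_on_equal_clouds(self, rng):
        pts = rng.normal(size=(30, 3))
        t = kabsch_align(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, 0.0, atol=1e-10)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(25, 3))
        t = kabsch_align(pts, pts + np.array([1.0, 2.0, 3.0]))
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, [1.0, 2.0, 3.0], atol=1e-10)

    def test_round_trip_recovers_known_transform(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        r = rodrigues_rotation([0.0, 0.0, 1.0], np.radians(30.0))
        t = np.array([4.0, -2.0, 1.0])
        rec = kabsch_align(pts, pts @ r.T + t)
        assert np.max(np.abs(rec.rotation - r)) < 1e-8
        assert np.max(np.abs(rec.translation - t)) < 1e-8

    def test_matches_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's weighted Kabsch on centered clouds."""
        src = rng.normal(size=(40, 3))
        dst = src @ random_rotation(rng).T + rng.normal(size=3)
        ours = kabsch_align(src, dst)
        rot, _ = ScipyRotation.align_vectors(dst - dst.mean(0), src - src.mean(0))
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-8)

    def test_reflection_corrected_to_proper_rotation(self, rng):
        src = rng.normal(size=(40, 3))
        mirrored = src * np.array([1.0, 1.0, -1.0])  # reflected target
        rec = kabsch_align(src, mirrored)
        assert np.linalg.det(rec.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "src,dst,match",
        [
            (np.zeros((4, 3)), np.zeros((5, 3)), "correspondence"),
            (np.zeros((2, 3)), np.zeros((2, 3)), "degenerate"),
            (np.outer(np.arange(6), [1.0, 0, 0]), np.outer(np.arange(6), [1.0, 0, 0]), "collinear"),
        ],
    )
    def test_error_contracts(self, src, dst, match):
        with pytest.raises(ValueError, match=match):
            kabsch_align(src, dst)


class TestRodrigues:
    def test_zero_angle_is_identity(self):
        assert np.allclose(rodrigues_rotation([1.0, 0, 0], 0.0), np.eye(3))

    def test_quarter_turn_about_z(self):
        expected = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(rodrigues_rotation([0, 0, 1.0], np.pi / 2), expected, atol=1e-12)

    def test_matches_quaternion_path(self, rng):
        """Same axis-angle through the quaternion route agrees to 1e-10."""
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-np.pi, np.pi)
            q = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
            assert np.max(np.abs(rodrigues_rotation(axis, angle) - quat_to_rotmat(q))) < 1e-10

    def test_properness_and_angle_recovery(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = 0.7
        r = rodrigues_rotation(axis, theta)
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)
        assert np.arccos((np.trace(r) - 1) / 2) == pytest.approx(theta, abs=1e-12)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            rodrigues_rotation([0.0, 0.0, 0.0], 0.5)


class TestQuaternions:
    def test_identity_round_trip(self):
        assert np.allclose(rotmat_to_quat(np.eye(3)), [1, 0, 0, 0])
        assert np.allclose(quat_to_rotmat([1.0, 0, 0, 0]), np.eye(3))

    def test_half_turn_about_x(self):
        r = rodrigues_rotation([1.0, 0, 0], np.pi)
        assert np.allclose(rotmat_to_quat(r), [0, 1, 0, 0], atol=1e-9)

    def test_random_round_trips_vs_scipy(self, rng):
        """1000 random rotations: round trip < 1e-9 and agrees with scipy."""
        rots = ScipyRotation.random(1000, rng=np.random.default_rng(5)).as_matrix()
        worst = 0.0
        for r in rots:
            q = rotmat_to_quat(r)
            assert q[0] >= 0  # canonical sign
            worst = max(worst, np.max(np.abs(quat_to_rotmat(q) - r)))
            q_scipy = ScipyRotation.from_matrix(r).as_quat()  # (x,y,z,w)
            q_scipy = np.roll(q_scipy, 1)
            if q_scipy[0] < 0:
                q_scipy = -q_scipy
            assert np.allclose(q, q_scipy, atol=1e-9)
        assert worst < 1e-9

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            rotmat_to_quat(np.eye(3) * 1.01)


class TestSlerp:
    def test_endpoints(self, rng):
        q0 = rotmat_to_quat(random_rotation(rng))
        q1 = rotmat_to_quat(random_rotation(rng))
        assert np.allclose(quat_slerp(q0, q1, 0.0), q0, atol=1e-12)
        assert np.allclose(quat_slerp(q0, q1, 1.0), q1, atol=1e-12)

    def test_halfway_angle(self):
        q1 = rotmat_to_quat(rodrigues_rotation([0, 0, 1.0], np.radians(10.0)))
        mid = quat_slerp([1.0, 0, 0, 0], q1, 0.5)
        angle = np.degrees(2 * np.arccos(np.clip(mid[0], -1, 1)))
        assert angle == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("u", [0.0, 0.25, 0.5, 0.9, 1.0])
    def test_double_cover_absorbed(self, u, rng):
        q = rotmat_to_quat(random_rotation(rng))
        out = quat_slerp(q, -q, u)
        assert min(np.linalg.norm(out - q), np.linalg.norm(out + q)) < 1e-9

    @pytest.mark.parametrize("theta_deg", [1.0, 45.0, 120.0, 179.0])
    @pytest.mark.parametrize("u", [0.1, 0.5, 0.8])
    def test_angle_linearity(self, theta_deg, u):
        q1 = rotmat_to_quat(rodrigues_rotation([0, 1.0, 0], np.radians(theta_deg)))
        out = quat_slerp([1.0, 0, 0, 0], q1, u)
        angle = np.degrees(2 * np.arccos(np.clip(abs(out[0]), -1, 1)))
        assert angle == pytest.approx(u * theta_deg, abs=1e-8)

    def test_fraction_range_checked(self):
        with pytest.raises(ValueError, match="fraction"):
            quat_slerp([1.0, 0, 0, 0], [1.0, 0, 0, 0], 1.5)


class TestTransforms:
    def test_identity_leaves_points(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.array_equal(transform_points(pts, RigidTransform.identity()), pts)

    def test_quarter_turn_single_point(self):
        t = RigidTransform(rodrigues_rotation([0, 0, 1.0], np.pi / 2))
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_rigidity_preserves_pairwise_distances(self, rng):
        pts = rng.normal(size=(40, 3)) * 20
        t = RigidTransform(random_rotation(rng), rng.normal(size=3) * 5)
        moved = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            transform_points(np.array([[np.nan, 0, 0]]), RigidTransform.identity())

    def test_compose_invert_identity(self, rng):
        a = RigidTransform(random_rotation(rng), rng.normal(size=3))
        b = RigidTransform(random_rotation(rng), rng.normal(size=3))
        c = RigidTransform(random_rotation(rng), rng.normal(size=3))
        left = a.compose(b).compose(c)
        right = a.compose(b.compose(c))
        assert left.almost_equal(right, atol=1e-9)
        assert a.inverse().compose(a).almost_equal(RigidTransform.identity(), atol=1e-9)

    def test_bottom_row_and_quaternion_view(self, rng):
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        assert np.array_equal(t.matrix[3], [0, 0, 0, 1])
        assert np.linalg.norm(t.quaternion) == pytest.approx(1.0, abs=1e-9)
        assert t.quaternion[0] >= 0


def test_transform_text_round_trip(tmp_path, rng):
    """Column-major plain-text serialization is lossless."""
    transforms = {
        0: RigidTransform(random_rotation(rng), rng.normal(size=3)),
        3: RigidTransform(random_rotation(rng), rng.normal(size=3)),
    }
    path = tmp_path / "t.txt"
    write_transform_text(path, transforms)
    back = read_transform_text(path)
    assert set(back) == {0, 3}
    for k in transforms:
        assert transforms[k].almost_equal(back[k], atol=1e-15)
    # serialized element order is column-major
    vals = [float(x) for x in path.read_text().splitlines()[1:17]]
    assert np.allclose(np.array(vals).reshape(4, 4, order="F"), transforms[0].matrix)
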