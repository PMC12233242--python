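"""Loss terms: closed forms, invariants, and analytic-vs-numeric gradients."""

import numpy as np
import pytest

from dentalign.autodiff import Tensor
from dentalign.losses import (
    LossWeights,
    chamfer_loss,
    core_loss,
    dof_loss,
    grid_distance_loss,
    joint_loss,
    reconstruction_loss,
    spatial_relation_loss,
)


def _lj(x):
    return x**-12 - 2.0 * x**-6


class TestGridDistance:
    def test_touching_pair_reaches_potential_well(self):
        """Shared closest point with sigma=0 puts x at 1, phi at -1, L_d at 1."""
        a = np.array([[0.0, 0, 0], [0.0, 0, 5]])
        b = np.array([[0.0, 0, 0], [0.0, 0, -5]])  # min distance exactly 0
        val = grid_distance_loss([np.stack([a, b])], [(0, 1)], sigma=0.0).item()
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_large_clearance_ratio_vanishes(self):
        """phi -> 0 as the clearance/centroid-distance ratio grows large."""
        a = np.zeros((3, 3))
        b = np.zeros((3, 3)) + np.array([10.0, 0.0, 0.0])
        val = grid_distance_loss([np.stack([a, b])], [(0, 1)], sigma=1e4).item()
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_separation_monotonically_relaxes_potential(self):
        """Pulling a touching pair apart moves phi from the well toward 0."""
        a = np.array([[x, y, z] for x in (-1.0, 1.0) for y in (-1.0, 1.0)
                      for z in (-1.0, 1.0)])
        vals = [
            grid_distance_loss(
                [np.stack([a, a + np.array([sep, 0.0, 0.0])])], [(0, 1)], sigma=0.0
            ).item()
            for sep in (2.5, 4.0, 10.0, 100.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_matches_independent_scalar_arithmetic(self):
        """Two engineered pairs vs a hand-rolled loop evaluation of the
        same closed form."""
        rng = np.random.default_rng(8)
        clouds = rng.normal(size=(3, 20, 3)) * 3 + np.arange(3)[:, None, None] * 8.0
        sigma = 0.2
        pairs = [(0, 1), (1, 2)]
        phis = []
        for i, j in pairs:
            pe = min(np.linalg.norm(p - q) for p in clouds[i] for q in clouds[j]) + sigma
            pc = np.linalg.norm(clouds[i].mean(0) - clouds[j].mean(0))
            phis.append(_lj(1.0 + pe / pc))
        expected = np.sqrt(np.mean(np.square(phis)))
        got = grid_distance_loss([clouds], pairs, sigma).item()
        assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            grid_distance_loss([np.zeros((2, 2, 3))], [(0, 1)], sigma=-0.1)


class TestCoreLoss:
    def test_identical_is_zero(self, rng):
        c = rng.normal(size=(5, 3))
        assert core_loss(c, c).item() == 0.0

    def test_single_offset_hand_value(self):
        assert core_loss(np.array([[2.0, 0, 0]]), np.zeros((1, 3))).item() == pytest.approx(4.0)

    def test_quadratic_scaling(self, rng):
        c = rng.normal(size=(6, 3))
        d = rng.normal(size=(6, 3))
        base = core_loss(c, d).item()
        doubled = core_loss(d + 2 * (c - d), d).item()
        assert doubled == pytest.approx(4.0 * base, rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            core_loss(rng.normal(size=(3, 3)), rng.normal(size=(4, 3)))


class TestChamfer:
    def test_hand_value_and_symmetry(self, rng):
        p1, p2 = [np.zeros((1, 3))], [np.array([[1.0, 0, 0]])]
        assert chamfer_loss(p1, p2).item() == pytest.approx(2.0)
        a, b = [rng.normal(size=(10, 3))], [rng.normal(size=(7, 3))]
        assert chamfer_loss(a, b).item() == pytest.approx(chamfer_loss(b, a).item(), rel=1e-12)

    def test_identical_clouds_zero(self, rng):
        a = rng.normal(size=(12, 3))
        assert chamfer_loss([a], [a]).item() == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chamfer_loss([np.zeros((0, 3))], [np.zeros((1, 3))])


class TestReconstruction:
    def test_perfect_is_zero(self, rng):
        x = rng.normal(size=(2, 9, 3))
        assert reconstruction_loss(x, x).item() == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_bounds(self, rng):
        x = rng.normal(size=(1, 30, 3))
        d = np.array([0.7, -0.2, 0.4])
        moved = x + d
        nn_only = reconstruction_loss(moved, x, gamma=1.0, alpha=0.0).item()
        cent_only = reconstruction_loss(moved, x, gamma=0.0, alpha=1.0).item()
        assert nn_only <= np.dot(d, d) + 1e-12
        assert cent_only == pytest.approx(np.dot(d, d), rel=1e-9)

    def test_alpha_zero_equals_one_sided_chamfer(self, rng):
        """With alpha=0 the term is the one-sided half of the chamfer sum,
        cross-checked by an independent numpy loop."""
        xv = rng.normal(size=(3, 15, 3))
        xt = rng.normal(size=(3, 12, 3))
        got = reconstruction_loss(xv, xt, gamma=1.0, alpha=0.0).item()
        expected = np.mean([
            np.mean([min(np.sum((p - q) ** 2) for q in xt[i]) for p in xv[i]])
            for i in range(3)
        ])
        assert got == pytest.approx(expected, rel=1e-9)


class TestDofLoss:
    def test_zero_error(self):
        assert dof_loss(np.zeros(5), np.zeros(5)).item() == 0.0

    def test_hand_value_linear_branch(self):
        assert dof_loss(np.array([2.0]), np.array([0.0]), beta=0.5).item() == pytest.approx(1.5)

    def test_continuity_at_unit_error(self):
        """Both branches give 0.5 at d=1 with beta=0.5; a fine grid around
        the switch shows no jump."""
        grid = np.linspace(0.9, 1.1, 201)
        vals = [dof_loss(np.array([d]), np.array([0.0]), beta=0.5).item() for d in grid]
        jumps = np.abs(np.diff(vals))
        assert np.max(jumps) < 2e-3  # ~ slope * step, no discontinuity
        assert dof_loss(np.array([1.0]), np.array([0.0]), beta=0.5).item() == pytest.approx(0.5)

    def test_invalid_beta(self):
        with pytest.raises(ValueError, match="beta"):
            dof_loss(np.zeros(2), np.zeros(2), beta=0.0)


class TestSpatialRelation:
    def test_perfect_prediction_zero(self, rng):
        q = np.array([[1.0, 0, 0, 0], [0.0, 1.0, 0, 0]])
        t = rng.normal(size=(2, 3))
        assert spatial_relation_loss(t, t, q, q).item() == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_invariance(self):
        q = np.array([[np.sqrt(0.5), np.sqrt(0.5), 0, 0]])
        t = np.zeros((1, 3))
        assert spatial_relation_loss(t, t, q, -q).item() == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_quaternions_hand_value(self):
        p = np.array([[1.0, 0, 0, 0]])
        g = np.array([[0.0, 1.0, 0, 0]])
        t = np.zeros((1, 3))
        assert spatial_relation_loss(t, t, p, g).item() == pytest.approx(1.0)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError, match="non-unit"):
            spatial_relation_loss(np.zeros((1, 3)), np.zeros((1, 3)),
                                  np.array([[2.0, 0, 0, 0]]), np.array([[1.0, 0, 0, 0]]))


def _joint_inputs(rng):
    xv = rng.normal(size=(4, 10, 3)) + np.arange(4)[:, None, None] * 9.0
    xt = xv + rng.normal(size=xv.shape) * 0.1
    pt = rng.normal(size=(4, 3))
    gt = rng.normal(size=(4, 3))
    pr = rng.normal(size=(4, 4))
    pr /= np.linalg.norm(pr, axis=1, keepdims=True)
    gr = rng.normal(size=(4, 4))
    gr /= np.linalg.norm(gr, axis=1, keepdims=True)
    return xv, xt, pt, gt, pr, gr


class TestJointLoss:
    def test_zero_weights_zero_total(self, rng):
        xv, xt, pt, gt, pr, gr = _joint_inputs(rng)
        total, _ = joint_loss(xv, xt, pt, gt, pr, gr, LossWeights(lambdas=(0,) * 6))
        assert total.item() == 0.0

    def test_one_hot_recovers_each_term(self, rng):
        xv, xt, pt, gt, pr, gr = _joint_inputs(rng)
        _, terms = joint_loss(xv, xt, pt, gt, pr, gr)
        for k, key in enumerate(terms):
            lam = tuple(1.0 if i == k else 0.0 for i in range(6))
            total, _ = joint_loss(xv, xt, pt, gt, pr, gr, LossWeights(lambdas=lam))
            assert total.item() == pytest.approx(terms[key].item(), rel=1e-12)

    def test_unit_weights_additivity(self, rng):
        xv, xt, pt, gt, pr, gr = _joint_inputs(rng)
        total, terms = joint_loss(xv, xt, pt, gt, pr, gr)
        assert total.item() == pytest.approx(sum(t.item() for t in terms.values()), abs=1e-12)

    def test_all_terms_nonnegative(self, rng):
        xv, xt, pt, gt, pr, gr = _joint_inputs(rng)
        _, terms = joint_loss(xv, xt, pt, gt, pr, gr)
        for k, v in terms.items():
            assert v.item() >= 0.0, k

    def test_supervised_terms_zero_for_perfect_prediction(self, zero_severity_case):
        """All five supervised terms vanish when the prediction equals the
        target; the collision potential stays small but nonzero on an arch
        (adjacent teeth always interact)."""
        from dentalign.fvamp import pack_cases

        packed = pack_cases([zero_severity_case], m=24)
        xv = packed["target_clouds"]
        total, terms = joint_loss(
            xv, packed["target_clouds"], packed["true_trans"], packed["true_trans"],
            packed["true_quats"], packed["true_quats"],
        )
        for key in ("L_core", "L_C", "L_build", "L_dof", "L_re"):
            assert terms[key].item() == pytest.approx(0.0, abs=1e-10), key
        assert 0.0 <= terms["L_d"].item() < 1.0


class TestGradients:
    """Analytic gradients of every term vs central finite differences.

    Inputs come from a dedicated seeded generator: finite differences are
    only valid away from nearest-neighbour ties and the smooth-L1 switch
    point, so the evaluation points must be reproducible.
    """

    @pytest.fixture()
    def rng(self):
        return np.random.default_rng(424242)

    @staticmethod
    def _check(fn, x0, rel_tol=1e-4, eps=1e-6):
        x = Tensor(x0.copy(), requires_grad=True)
        fn(x).backward()
        analytic = x.grad.copy()
        flat = x0.ravel()
        numeric = np.zeros_like(flat)
        for i in range(flat.size):
            for sign in (+1, -1):
                pert = flat.copy()
                pert[i] += sign * eps
                numeric[i] += sign * fn(Tensor(pert.reshape(x0.shape))).item()
        numeric /= 2 * eps
        numeric = numeric.reshape(x0.shape)
        denom = np.maximum(np.abs(numeric), 1e-6)
        assert np.max(np.abs(analytic - numeric) / denom) < rel_tol

    def test_grid_distance_gradient(self, rng):
        clouds = rng.normal(size=(3, 6, 3)) * 2 + np.arange(3)[:, None, None] * 7.0
        self._check(lambda x: grid_distance_loss(x, [(0, 1), (1, 2)], 0.2), clouds)

    def test_core_gradient(self, rng):
        d = rng.normal(size=(5, 3))
        self._check(lambda x: core_loss(x, d), rng.normal(size=(5, 3)))

    def test_chamfer_gradient(self, rng):
        b = rng.normal(size=(8, 3))
        self._check(lambda x: chamfer_loss(x, Tensor(b)), rng.normal(size=(6, 3)))

    def test_reconstruction_gradient(self, rng):
        xt = rng.normal(size=(2, 7, 3))
        self._check(lambda x: reconstruction_loss(x, xt, 0.8, 0.3), rng.normal(size=(2, 7, 3)))

    def test_dof_gradient(self, rng):
        g = rng.normal(size=(4, 7))
        x0 = g + rng.normal(size=(4, 7))  # random errors straddling d=1
        x0[np.abs(np.abs(x0 - g) - 1.0) < 1e-3] += 0.01  # stay off the switch point
        self._check(lambda x: dof_loss(x, g, 0.5), x0)

    def test_spatial_relation_gradient_wrt_translation(self, rng):
        gt = rng.normal(size=(4, 3))
        q = rng.normal(size=(4, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        self._check(lambda x: spatial_relation_loss(x, gt, q, q), rng.normal(size=(4, 3)))

    def test_joint_gradient_wrt_predicted_clouds(self, rng):
        """Summed-loss gradient against finite differences with a mixed
        absolute/relative tolerance: opposing terms (collision vs
        chamfer) can nearly cancel, leaving components too small for a
        purely relative comparison."""
        xv, xt, pt, gt, pr, gr = _joint_inputs(rng)

        def fn(x):
            return joint_loss(x, xt, pt, gt, pr, gr)[0]

        x = Tensor(xv.copy(), requires_grad=True)
        fn(x).backward()
        flat = xv.ravel()
        num = np.zeros_like(flat)
        eps = 1e-6
        for i in range(flat.size):
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            num[i] = (fn(Tensor(up.reshape(xv.shape))).item()
                      - fn(Tensor(dn.reshape(xv.shape))).item()) / (2 * eps)
        num = num.reshape(xv.shape)
        assert np.max(np.abs(x.grad - num) / (1.0 + np.abs(num))) < 1e-4
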