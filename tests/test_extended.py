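"""Articulated head model, dual 3DMM, SH shading, and the loss functions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morphfit.exceptions import (
    InvalidInputError,
    MissingTermError,
    UndefinedLossError,
)
from morphfit.extended import (
    SH_CONSTANTS,
    ArticulatedModel,
    articulated_deform,
    coarse_loss,
    coef_reg_loss,
    detail_loss,
    detail_reg_loss,
    dual_3dmm,
    eye_closure_loss,
    landmark_loss,
    perception_loss,
    photometric_loss,
    sh_basis,
    sh_radiosity,
    shape_consistency_loss,
    symmetry_loss,
    texture_flatten_loss,
)
from morphfit.landmarks import EYELID_PAIRS


# ---------------------------------------------------------------------------
# articulated model


def _toy_articulated(n_shape=2, n_expr=2, rng=None):
    """8 vertices, 4 joints (2 meaningfully weighted + 2 passive)."""
    rng = rng or np.random.default_rng(0)
    template = rng.normal(0, 10, 24)
    joints = np.array(
        [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [0.0, 5.0, 0.0], [0.0, -5.0, 0.0]]
    )
    parents = np.array([-1, -1, -1, -1])  # all joints attached to the root
    w = rng.random((4, 8))
    w /= w.sum(axis=0)
    return ArticulatedModel(
        template=template,
        shape_basis=rng.normal(size=(24, n_shape)),
        pose_basis=np.zeros((24, 36)),
        expr_basis=rng.normal(size=(24, n_expr)),
        joints=joints,
        parents=parents,
        skin_weights=w,
        faces=np.array([[0, 1, 2]]),
    )


class TestArticulatedDeform:
    def test_rest_pose_returns_template_exactly(self):
        model = _toy_articulated()
        out = articulated_deform(model, np.zeros(2), np.zeros(2), np.zeros(15))
        np.testing.assert_array_equal(
            out.vertices.reshape(-1), model.template
        )

    def test_global_rotation_is_rigid(self):
        model = _toy_articulated()
        theta = np.zeros(15)
        theta[:3] = [0.3, -0.2, 0.5]
        out = articulated_deform(model, np.zeros(2), np.zeros(2), theta)
        rest = model.template.reshape(-1, 3)
        # pairwise distances preserved
        def pdist(v):
            return np.linalg.norm(v[:, None] - v[None, :], axis=-1)
        np.testing.assert_allclose(pdist(out.vertices), pdist(rest), atol=1e-8)
        # and equals the explicit rigid rotation
        R = Rotation.from_rotvec(theta[:3]).as_matrix()
        np.testing.assert_allclose(out.vertices, rest @ R.T, atol=1e-10)

    def test_matches_brute_force_lbs_oracle(self, rng):
        """Hand-coded per-vertex weighted-transform computation."""
        model = _toy_articulated(rng=rng)
        beta = rng.normal(size=2)
        psi = rng.normal(size=2)
        theta = rng.normal(0, 0.4, 15)
        out = articulated_deform(model, beta, psi, theta)

        shaped = (
            model.template
            + model.shape_basis @ beta
            + model.expr_basis @ psi
        ).reshape(-1, 3)
        Rg = Rotation.from_rotvec(theta[:3]).as_matrix()
        expected = np.zeros_like(shaped)
        for j in range(4):
            Rj = Rotation.from_rotvec(theta[3 + 3 * j : 6 + 3 * j]).as_matrix()
            Jp = model.joints[j]
            for v in range(8):
                local = Jp + Rj @ (shaped[v] - Jp)
                expected[v] += model.skin_weights[j, v] * (Rg @ local)
        np.testing.assert_allclose(out.vertices, expected, atol=1e-10)

    def test_parent_chain_composes(self):
        """A vertex skinned to a child joint feels the parent's rotation:
        rotating only the parent swings the child's vertices about the
        parent's position."""
        template = np.array([[10.0, 0.0, 0.0], [6.0, 1.0, 0.0],
                             [7.0, -2.0, 3.0]]).reshape(-1)
        joints = np.array([[2.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        parents = np.array([-1, 0])
        w = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])  # all on the child
        model = ArticulatedModel(
            template=template,
            shape_basis=np.zeros((9, 1)),
            pose_basis=np.zeros((9, 18)),
            expr_basis=np.zeros((9, 1)),
            joints=joints,
            parents=parents,
            skin_weights=w,
            faces=np.array([[0, 1, 2]]),
        )
        theta = np.zeros(9)
        theta[3:6] = [0.0, 0.0, np.pi / 2]  # parent joint only
        out = articulated_deform(model, [0.0], [0.0], theta)
        R = Rotation.from_rotvec(theta[3:6]).as_matrix()
        expected = joints[0] + (template.reshape(-1, 3) - joints[0]) @ R.T
        np.testing.assert_allclose(out.vertices, expected, atol=1e-10)

    def test_bad_weights_rejected(self, rng):
        model = _toy_articulated(rng=rng)
        with pytest.raises(InvalidInputError):
            ArticulatedModel(
                template=model.template,
                shape_basis=model.shape_basis,
                pose_basis=model.pose_basis,
                expr_basis=model.expr_basis,
                joints=model.joints,
                parents=model.parents,
                skin_weights=model.skin_weights * 2.0,
                faces=model.faces,
            )


# ---------------------------------------------------------------------------
# dual 3DMM


class TestDual3DMM:
    def test_zero_coeffs_give_means(self, rng):
        S0, T0 = rng.normal(size=12), rng.normal(size=12)
        S, T = dual_3dmm(
            S0, T0, rng.normal(size=(12, 3)), rng.normal(size=(12, 2)),
            rng.normal(size=(12, 4)), np.zeros(3), np.zeros(2), np.zeros(4),
        )
        np.testing.assert_array_equal(S, S0)
        np.testing.assert_array_equal(T, T0)

    def test_superposition(self, rng):
        S0, T0 = rng.normal(size=12), rng.normal(size=12)
        bases = (rng.normal(size=(12, 3)), rng.normal(size=(12, 2)),
                 rng.normal(size=(12, 4)))
        a1, a2 = rng.normal(size=3), rng.normal(size=3)

        def shape(a):
            return dual_3dmm(S0, T0, *bases, a, np.zeros(2), np.zeros(4))[0]

        np.testing.assert_allclose(
            shape(a1 + a2) - shape(a1) - shape(a2) + shape(np.zeros(3)),
            0.0, atol=1e-10,
        )

    def test_matches_explicit_arithmetic(self, rng):
        S0, T0 = rng.normal(size=12), rng.normal(size=9)
        Bid = rng.normal(size=(12, 3))
        Bexp = rng.normal(size=(12, 2))
        Bt = rng.normal(size=(9, 4))
        a, b, d = rng.normal(size=3), rng.normal(size=2), rng.normal(size=4)
        S, T = dual_3dmm(S0, T0, Bid, Bexp, Bt, a, b, d)
        np.testing.assert_allclose(S, S0 + Bid @ a + Bexp @ b, atol=1e-12)
        np.testing.assert_allclose(T, T0 + Bt @ d, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InvalidInputError):
            dual_3dmm(np.zeros(12), np.zeros(12), np.zeros((12, 3)),
                      np.zeros((12, 2)), np.zeros((12, 4)),
                      np.zeros(4), np.zeros(2), np.zeros(4))


# ---------------------------------------------------------------------------
# spherical harmonics


class TestSHRadiosity:
    def test_nine_basis_functions(self, rng):
        n = rng.normal(size=(10, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert sh_basis(n).shape == (10, 9)

    def test_ambient_term_ignores_normal(self, rng):
        n = rng.normal(size=(10, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        tex = rng.random(10)
        gamma = np.zeros(9)
        gamma[0] = 3.0
        out = sh_radiosity(n, tex, gamma)
        np.testing.assert_allclose(out, tex * 3.0 * SH_CONSTANTS["c0"], atol=1e-12)

    def test_zero_texture_gives_zero(self, rng):
        n = rng.normal(size=(5, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        out = sh_radiosity(n, np.zeros(5), rng.normal(size=9))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_term_by_term_oracle(self, rng):
        """Independent per-term evaluation from the shared constant table."""
        n = rng.normal(size=(20, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        tex = rng.random(20)
        gamma = rng.normal(size=9)
        c = SH_CONSTANTS
        expected = []
        for (x, y, z), t in zip(n, tex):
            terms = [
                c["c0"], c["c1"] * y, c["c1"] * z, c["c1"] * x,
                c["c2"] * x * y, c["c2"] * y * z, c["c3"] * (3 * z * z - 1),
                c["c2"] * x * z, c["c4"] * (x * x - y * y),
            ]
            expected.append(t * sum(g * phi for g, phi in zip(gamma, terms)))
        np.testing.assert_allclose(
            sh_radiosity(n, tex, gamma), expected, atol=1e-12
        )

    def test_non_unit_normal_rejected(self):
        with pytest.raises(InvalidInputError):
            sh_basis(np.array([[1.0, 1.0, 0.0]]))


# ---------------------------------------------------------------------------
# losses


class TestPhotometricLoss:
    def test_identical_images_zero(self, rng):
        I = rng.random((8, 8, 3))
        A = np.ones((8, 8))
        assert photometric_loss(I, I, A, A) == 0.0

    def test_constant_offset_closed_form(self, rng):
        I = rng.random((6, 6, 3))
        c = 0.125
        loss = photometric_loss(I, I + c, np.ones((6, 6)), np.ones((6, 6)))
        assert loss == pytest.approx(c * np.sqrt(3), rel=1e-12)

    def test_matches_double_loop_reference(self, rng):
        I = rng.random((5, 7, 3))
        J = rng.random((5, 7, 3))
        A = rng.random((5, 7))
        M = (rng.random((5, 7)) > 0.4).astype(float)
        num = den = 0.0
        for i in range(5):
            for j in range(7):
                if M[i, j]:
                    num += A[i, j] * np.linalg.norm(I[i, j] - J[i, j])
                    den += A[i, j]
        assert photometric_loss(I, J, A, M) == pytest.approx(num / den, rel=1e-12)

    def test_pixel_permutation_invariance(self, rng):
        I = rng.random((40, 3))
        J = rng.random((40, 3))
        A = rng.random(40)
        M = np.ones(40)
        perm = rng.permutation(40)
        assert photometric_loss(I, J, A, M) == pytest.approx(
            photometric_loss(I[perm], J[perm], A[perm], M[perm]), rel=1e-12
        )

    def test_empty_mask_rejected(self, rng):
        I = rng.random((4, 4, 3))
        with pytest.raises(UndefinedLossError):
            photometric_loss(I, I, np.ones((4, 4)), np.zeros((4, 4)))


class TestLandmarkLoss:
    def test_exact_match_zero(self, rng):
        q = rng.random((68, 2))
        assert landmark_loss(q, q) == 0.0

    def test_single_mouth_point_closed_form(self):
        q = np.zeros((68, 2))
        q_proj = q.copy()
        q_proj[50] = [3.0, 4.0]  # slot 50 is a mouth point
        assert landmark_loss(q, q_proj) == pytest.approx(20.0 * 5.0 / 68.0)

    def test_non_mouth_nose_points_have_zero_default_weight(self):
        q = np.zeros((68, 2))
        q_proj = q.copy()
        q_proj[0] = [100.0, 100.0]  # jaw point
        assert landmark_loss(q, q_proj) == 0.0

    def test_matches_loop_oracle(self, rng):
        q = rng.random((68, 2))
        qp = rng.random((68, 2))
        w = rng.random(68)
        expected = sum(
            w[n] * np.linalg.norm(q[n] - qp[n]) for n in range(68)
        ) / 68
        assert landmark_loss(q, qp, w) == pytest.approx(expected, rel=1e-12)


class TestPerceptionLoss:
    def test_colinear_zero(self, rng):
        f = rng.normal(size=128)
        assert perception_loss(f, 2.0 * f) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_one(self):
        assert perception_loss([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_antipodal_two(self, rng):
        f = rng.normal(size=16)
        assert perception_loss(f, -f) == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        f, g = rng.normal(size=32), rng.normal(size=32)
        assert perception_loss(f, g) == pytest.approx(
            perception_loss(5.0 * f, 0.01 * g), rel=1e-10
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedLossError):
            perception_loss(np.zeros(4), np.ones(4))


class TestCoefAndTextureLosses:
    def test_zero_coeffs_zero(self):
        assert coef_reg_loss([], [], []) == 0.0

    def test_alpha_only(self):
        assert coef_reg_loss([1.0, 0.0], [], []) == pytest.approx(1.0)

    def test_unit_vectors_printed_weights(self):
        assert coef_reg_loss([1.0], [1.0], [1.0]) == pytest.approx(1.8017)

    def test_constant_texture_flat(self):
        tex = np.full((10, 3), 0.7)
        assert texture_flatten_loss(tex, np.arange(10)) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_two_vertex_region_closed_form(self):
        tex = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        assert texture_flatten_loss(tex, [0, 1]) == pytest.approx(3.0)

    def test_matches_variance_oracle(self, rng):
        tex = rng.random((30, 3))
        region = rng.choice(30, 12, replace=False)
        expected = sum(np.var(tex[region, c]) for c in range(3))
        assert texture_flatten_loss(tex, region) == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_region_rejected(self, rng):
        with pytest.raises(UndefinedLossError):
            texture_flatten_loss(rng.random((5, 3)), [])


class TestAggregateLosses:
    def test_all_zero_components(self):
        assert coarse_loss(0, 0, 0, 0, 0, 0) == 0.0
        assert detail_loss(0, 0, 0) == 0.0

    def test_single_nonzero_component_passes_through(self):
        assert coarse_loss(0, 0, 1.25, 0, 0, 0) == pytest.approx(1.25)
        assert detail_loss(0, 0.5, 0) == pytest.approx(0.5)

    def test_missing_component_named(self):
        with pytest.raises(MissingTermError, match="identity"):
            coarse_loss(landmark=0, eye=0, photometric=0,
                        shape_consistency=0, regularization=0)

    def test_symmetric_displacement_zero_symmetry(self, rng):
        D = rng.random((6, 5))
        D = 0.5 * (D + D[:, ::-1])
        assert symmetry_loss(D) == pytest.approx(0.0, abs=1e-12)

    def test_eye_closure_zero_on_exact_match(self, rng):
        pts = rng.random((68, 2))
        assert eye_closure_loss(pts, pts, EYELID_PAIRS) == 0.0

    def test_shape_consistency_and_detail_reg(self, rng):
        b = rng.normal(size=5)
        assert shape_consistency_loss(b, b) == 0.0
        D = rng.random((4, 4))
        assert detail_reg_loss(D) == pytest.approx((D**2).sum())

    def test_all_losses_nonnegative(self, rng):
        I, J = rng.random((4, 4, 3)), rng.random((4, 4, 3))
        A = np.ones((4, 4))
        assert photometric_loss(I, J, A, A) >= 0
        assert landmark_loss(rng.random((68, 2)), rng.random((68, 2))) >= 0
        assert perception_loss(rng.normal(size=8), rng.normal(size=8)) >= 0
        assert coef_reg_loss(rng.normal(size=3), rng.normal(size=2),
                             rng.normal(size=4)) >= 0
        assert texture_flatten_loss(rng.random((6, 3)), [0, 1, 2]) >= 0
        assert symmetry_loss(rng.random((5, 5))) >= 0


class TestLossInputIO:
    def test_npz_round_trip(self, rng, tmp_path):
        from morphfit.extended import load_loss_inputs

        path = tmp_path / "inputs.npz"
        I = rng.random((4, 4, 3))
        A = rng.random((4, 4))
        np.savez(path, raw_image=I, attention=A)
        back = load_loss_inputs(path)
        np.testing.assert_array_equal(back["raw_image"], I)
        np.testing.assert_array_equal(back["attention"], A)

    def test_png_image_rescaled_to_unit_range(self, rng, tmp_path):
        from PIL import Image

        from morphfit.extended import load_image

        arr = rng.integers(0, 256, (5, 6, 3), dtype=np.uint8)
        path = tmp_path / "img.png"
        Image.fromarray(arr).save(path)
        out = load_image(path)
        assert out.shape == (5, 6, 3)
        np.testing.assert_allclose(out, arr / 255.0, atol=1e-12)

    def test_yaml_weights(self, tmp_path):
        from morphfit.extended import coarse_loss, load_loss_weights

        path = tmp_path / "weights.yaml"
        path.write_text("photometric: 2.0\nlandmark: 0.5\n")
        w = load_loss_weights(path)
        total = coarse_loss(1.0, 0.0, 1.0, 0.0, 0.0, 0.0, weights=w)
        assert total == pytest.approx(0.5 + 2.0)
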