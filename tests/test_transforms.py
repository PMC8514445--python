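"""Affine/similarity/piecewise fits and dense deformation application."""

import numpy as np
import pytest

from mesomap.registration import (
    AffineMap2D,
    apply_deformation,
    compose,
    fit_affine_multi,
    fit_affine_three,
    fit_piecewise_affine,
    fit_similarity_two,
    invert,
    warp_image,
)


class TestFitAffineThree:
    def test_identity(self):
        pts = np.array([[0, 0], [0, 5], [5, 0]], float)
        m = fit_affine_three(pts, pts)
        assert np.allclose(m.matrix, AffineMap2D.identity().matrix, atol=1e-12)

    def test_rotation_closed_form(self):
        # 90 deg rotation about the origin in (row, col): (r, c) -> (c, -r)
        src = np.array([[0, 0], [1, 0], [0, 1]], float)
        dst = np.array([[0, 0], [0, -1], [1, 0]], float)
        m = fit_affine_three(src, dst)
        assert np.allclose(m.matrix, [[0, 1, 0], [-1, 0, 0]], atol=1e-12)

    def test_random_exactness_vs_linear_system(self, rng):
        # independent oracle: solve the full 6x6 linear system
        for _ in range(20):
            src = rng.uniform(0, 100, (3, 2))
            dst = rng.uniform(0, 100, (3, 2))
            if abs(np.linalg.det(np.column_stack([src, np.ones(3)]))) < 1e-3:
                continue
            a = np.zeros((6, 6))
            b = np.zeros(6)
            for i, (s, d) in enumerate(zip(src, dst)):
                a[2 * i, :2] = s
                a[2 * i, 4] = 1
                a[2 * i + 1, 2:4] = s
                a[2 * i + 1, 5] = 1
                b[2 * i], b[2 * i + 1] = d
            x = np.linalg.solve(a, b)
            oracle = np.array([[x[0], x[1], x[4]], [x[2], x[3], x[5]]])
            m = fit_affine_three(src, dst)
            assert np.allclose(m.matrix, oracle, atol=1e-8)
            assert np.linalg.norm(m.apply(src) - dst) < 1e-9

    def test_collinear_error(self):
        src = np.array([[0, 0], [1, 1], [2, 2]], float)
        with pytest.raises(ValueError, match="collinear"):
            fit_affine_three(src, src + 1)


class TestFitSimilarityTwo:
    def test_pure_scale(self):
        src = np.array([[0, 0], [0, 1]], float)
        dst = np.array([[0, 0], [0, 2]], float)
        m = fit_similarity_two(src, dst)
        assert np.allclose(m.linear, 2 * np.eye(2), atol=1e-12)
        assert np.allclose(m.translation, 0, atol=1e-12)

    def test_pure_rotation(self):
        # (0,0)->(0,0) and col-unit -> row-unit: a 90 deg rotation, scale 1
        src = np.array([[0, 0], [0, 1]], float)
        dst = np.array([[0, 0], [1, 0]], float)
        m = fit_similarity_two(src, dst)
        s = np.linalg.svd(m.linear, compute_uv=False)
        assert np.allclose(s, [1, 1], atol=1e-12)
        assert np.allclose(m.apply(src), dst, atol=1e-12)

    def test_uniform_scale_no_reflection(self, rng):
        for _ in range(100):
            src = rng.uniform(-50, 50, (2, 2))
            dst = rng.uniform(-50, 50, (2, 2))
            if np.allclose(src[0], src[1]) or np.allclose(dst[0], dst[1]):
                continue
            m = fit_similarity_two(src, dst)
            s = np.linalg.svd(m.linear, compute_uv=False)
            assert s[0] == pytest.approx(s[1], rel=1e-9)  # uniform scale
            assert np.linalg.det(m.linear) > 0  # no reflection
            assert np.linalg.norm(m.apply(src) - dst) < 1e-9

    def test_coincident_error(self):
        src = np.array([[1, 1], [1, 1]], float)
        with pytest.raises(ValueError, match="coincide"):
            fit_similarity_two(src, src)


class TestFitAffineMulti:
    def test_recovers_generating_affine(self, rng):
        truth = AffineMap2D(np.array([[1.1, 0.2, 3.0], [-0.1, 0.9, -2.0]]))
        src = rng.uniform(0, 100, (8, 2))
        dst = truth.apply(src)
        m = fit_affine_multi(src, dst)
        assert np.allclose(m.matrix, truth.matrix, atol=1e-9)
        assert np.linalg.norm(m.apply(src) - dst) < 1e-9

    def test_three_points_equals_exact_fit(self, rng):
        src = rng.uniform(0, 10, (3, 2))
        dst = rng.uniform(0, 10, (3, 2))
        assert np.allclose(
            fit_affine_multi(src, dst).matrix, fit_affine_three(src, dst).matrix,
            atol=1e-8,
        )

    def test_least_squares_optimality(self, rng):
        # randomized check: no perturbed affine does better on noisy data
        src = rng.uniform(0, 100, (10, 2))
        truth = AffineMap2D(np.array([[1.0, 0.1, 5.0], [0.0, 1.0, -3.0]]))
        dst = truth.apply(src) + rng.normal(0, 2.0, (10, 2))
        m = fit_affine_multi(src, dst)
        base = np.sum((m.apply(src) - dst) ** 2)
        for _ in range(1000):
            cand = AffineMap2D(m.matrix + rng.normal(0, 0.01, (2, 3)))
            assert np.sum((cand.apply(src) - dst) ** 2) >= base - 1e-9

    def test_rank_deficient_error(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError, match="collinear"):
            fit_affine_multi(src, src)


class TestComposeInvert:
    def test_identity_neutral(self, rng):
        m = AffineMap2D(rng.uniform(-1, 1, (2, 3)) + np.array([[2, 0, 0], [0, 2, 0]]))
        ident = AffineMap2D.identity()
        assert np.allclose(compose(ident, m).matrix, m.matrix)
        assert np.allclose(compose(m, ident).matrix, m.matrix)

    def test_invert_rotation(self):
        th = np.deg2rad(30)
        rot = AffineMap2D(
            np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0]])
        )
        inv = invert(rot)
        expected = np.array([[np.cos(-th), -np.sin(-th), 0], [np.sin(-th), np.cos(-th), 0]])
        assert np.allclose(inv.matrix, expected, atol=1e-12)

    def test_compose_matches_matrix_product(self, rng):
        for _ in range(20):
            a = AffineMap2D(rng.uniform(-1, 1, (2, 3)) + np.array([[2.0, 0, 0], [0, 2.0, 0]]))
            b = AffineMap2D(rng.uniform(-1, 1, (2, 3)) + np.array([[2.0, 0, 0], [0, 2.0, 0]]))
            # oracle: 3x3 homogeneous matrix product
            ha = np.vstack([a.matrix, [0, 0, 1]])
            hb = np.vstack([b.matrix, [0, 0, 1]])
            assert np.allclose(compose(a, b).matrix, (ha @ hb)[:2], atol=1e-12)
            assert np.allclose(
                compose(a, invert(a)).matrix, AffineMap2D.identity().matrix, atol=1e-9
            )

    def test_equivariance_under_rigid_conjugation(self, rng):
        # conjugating inputs by a rigid transform conjugates the fitted map
        th = np.deg2rad(17)
        g = AffineMap2D(
            np.array([[np.cos(th), -np.sin(th), 4.0], [np.sin(th), np.cos(th), -7.0]])
        )
        src = rng.uniform(0, 50, (3, 2))
        dst = rng.uniform(0, 50, (3, 2))
        m = fit_affine_three(src, dst)
        m_conj = fit_affine_three(g.apply(src), g.apply(dst))
        expected = compose(g, compose(m, invert(g)))
        assert np.allclose(m_conj.matrix, expected.matrix, atol=1e-6)


class TestPiecewiseAffine:
    def test_identity_on_hull(self, rng):
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], float)
        m = fit_piecewise_affine(pts, pts)
        probe = rng.uniform(0, 10, (50, 2))
        assert np.abs(m.apply(probe) - probe).max() < 1e-9

    def test_three_pairs_equal_affine(self, rng):
        src = np.array([[0, 0], [0, 10], [10, 0]], float)
        dst = np.array([[1, 2], [0, 12], [11, -1]], float)
        pw = fit_piecewise_affine(src, dst)
        aff = fit_affine_three(src, dst)
        probe = np.array([[1, 1], [2, 3], [5, 2], [8, 1], [3, 3]], float)
        assert np.abs(pw.apply(probe) - aff.apply(probe)).max() < 1e-9

    def test_square_with_displaced_corner_per_triangle_oracle(self):
        src = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float)
        dst = src.copy()
        dst[2] = [12, 13]  # displace one corner
        pw = fit_piecewise_affine(src, dst)
        for simplex in pw.tri.simplices:
            tri_src = src[simplex]
            tri_dst = dst[simplex]
            oracle = fit_affine_three(tri_src, tri_dst)
            probe = tri_src.mean(axis=0, keepdims=True)  # strictly inside
            assert np.abs(pw.apply(probe) - oracle.apply(probe)).max() < 1e-9

    def test_control_points_exact(self, rng):
        src = rng.uniform(0, 100, (8, 2))
        dst = src + rng.normal(0, 3, (8, 2))
        pw = fit_piecewise_affine(src, dst)
        assert np.abs(pw.apply(src) - dst).max() < 1e-9

    def test_extrapolation_defined_outside_hull(self):
        src = np.array([[0, 0], [0, 10], [10, 0]], float)
        pw = fit_piecewise_affine(src, src + 1)
        out = pw.apply(np.array([[50.0, 50.0]]))
        assert np.all(np.isfinite(out))

    def test_collinear_error(self):
        src = np.array([[0, 0], [1, 1], [2, 2]], float)
        with pytest.raises(ValueError):
            fit_piecewise_affine(src, src)


class TestApplyDeformation:
    def test_zero_field_identity(self, rng):
        img = rng.uniform(0, 255, (20, 30))
        field = np.zeros((2, 20, 30))
        assert np.allclose(apply_deformation(field, img), img)

    def test_constant_shift(self):
        img = np.zeros((10, 10))
        img[7, 3] = 1.0
        field = np.zeros((2, 10, 10))
        field[0] = 5.0  # out(p) = in(p + 5 rows)
        out = apply_deformation(field, img, "nearest")
        assert out[2, 3] == 1.0
        assert out[7, 3] == 0.0
        assert out[5:].sum() == 0.0  # rows sampling past the border fill 0

    def test_affine_as_field_oracle(self, clean_scene):
        from mesomap.registration import AffineMap2D, invert, warp_image

        m = AffineMap2D(np.array([[0.95, 0.05, 3.0], [-0.04, 1.02, -2.0]]))
        labels = clean_scene.true_labels
        h, w = labels.shape
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        src = invert(m).apply(pts)
        field = (src - pts).T.reshape(2, h, w)
        via_field = apply_deformation(field, labels, "nearest")
        via_affine = warp_image(m, labels.astype(float), order=0).astype(labels.dtype)
        disagree = np.mean(via_field != via_affine)
        assert disagree < 0.01

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            apply_deformation(np.zeros((2, 5, 5)), np.zeros((6, 6)))


def test_warp_image_round_trip(clean_scene):
    m = AffineMap2D(np.array([[1.05, 0.0, 2.0], [0.0, 1.05, -1.0]]))
    warped = warp_image(m, clean_scene.image)
    back = warp_image(invert(m), warped)
    mask = clean_scene.true_mask > 0
    inner = np.zeros_like(mask)
    inner[10:-10, 10:-10] = True
    sel = mask & inner
    assert np.abs(back - clean_scene.image)[sel].mean() < 5.0
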