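"""Transform algebra: exact group operations, log-Euclidean combination,
B-spline evaluation against a brute-force basis oracle, serialization."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tdrecon import (Affine, BSplineTransform, ControlGrid, GridMismatchError,
                     InvalidTransformError, NonRealLogarithmError,
                     OutOfDomainError, SingularTransformError, Translation,
                     combine_affine, combine_translation, compose, invert,
                     transform_from_dict, transform_to_dict)


class TestTranslation:
    @pytest.mark.parametrize("da, db, alpha, expected", [
        ((1, 0), (1, 0), 0.45, (0.9, 0)),
        ((0, 0), (0, 0), 0.45, (0, 0)),
        ((2, -2), (-2, 2), 0.3, (0, 0)),
    ])
    def test_combine(self, da, db, alpha, expected):
        out = combine_translation(Translation(da), Translation(db), alpha)
        np.testing.assert_allclose(out.delta, expected, atol=1e-15)

    def test_compose_is_vector_addition(self):
        out = compose(Translation((1, 2)), Translation((3, -1)))
        np.testing.assert_array_equal(out.delta, [4, 1])

    def test_invert_is_negation(self):
        t = Translation((2.5, -1.5))
        np.testing.assert_array_equal(invert(t).delta, [-2.5, 1.5])
        np.testing.assert_array_equal(compose(t, invert(t)).delta, [0, 0])

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidTransformError):
            Translation((np.nan, 0))
        with pytest.raises(InvalidTransformError):
            combine_translation(Translation((1, 0)), Translation((1, 0)), np.inf)

    def test_one_dimensional_mode(self):
        t = compose(Translation(1.5), Translation(-0.5))
        assert t.delta.shape == (1,)
        assert t.delta[0] == 1.0


class TestAffine:
    def test_combine_identity(self):
        out = combine_affine(Affine.identity(), Affine.identity(), 0.3)
        np.testing.assert_allclose(out.matrix, np.eye(3), atol=1e-14)

    def test_combine_scaling_closed_form(self):
        s = Affine.scaling(2.0)
        out = combine_affine(s, s, 0.45)
        np.testing.assert_allclose(out.matrix[0, 0], 2.0 ** 0.9, rtol=1e-12)
        np.testing.assert_allclose(out.matrix[1, 1], 2.0 ** 0.9, rtol=1e-12)

    def test_combine_opposite_rotations_cancel(self):
        out = combine_affine(Affine.rotation(10), Affine.rotation(-10), 0.45)
        np.testing.assert_allclose(out.matrix, np.eye(3), atol=1e-10)

    def test_scaling_invert(self):
        np.testing.assert_allclose(invert(Affine.scaling(2.0)).matrix,
                                   np.diag([0.5, 0.5, 1.0]), atol=1e-14)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_compose_invert_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        m = np.eye(3)
        m[:2, :2] = np.eye(2) + 0.3 * rng.uniform(-1, 1, (2, 2))
        m[:2, 2] = rng.uniform(-10, 10, 2)
        f = Affine(m)
        np.testing.assert_allclose(compose(f, invert(f)).matrix, np.eye(3),
                                   atol=1e-10)

    def test_reduces_to_translation_combination(self):
        a, b = Translation((1.5, -2.0)), Translation((0.5, 3.0))
        expect = combine_translation(a, b, 0.45)
        out = combine_affine(a.as_affine(), b.as_affine(), 0.45)
        np.testing.assert_allclose(out.matrix[:2, 2], expect.delta, atol=1e-12)
        np.testing.assert_allclose(out.matrix[:2, :2], np.eye(2), atol=1e-12)

    def test_half_turn_has_no_real_log(self):
        with pytest.raises(NonRealLogarithmError):
            Affine.rotation(180).log()

    def test_rotation_plus_anisometric_scaling_has_no_real_log(self):
        # R(120 deg) @ diag(4, 1/4) has two negative real eigenvalues
        m = Affine.rotation(120).compose(Affine.scaling((4.0, 0.25)))
        assert np.all(np.linalg.eigvals(m.matrix[:2, :2]).real < 0)
        with pytest.raises(NonRealLogarithmError):
            combine_affine(m, Affine.identity(), 0.45)

    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        with pytest.raises(SingularTransformError):
            Affine(m)

    def test_last_row_enforced(self):
        with pytest.raises(InvalidTransformError):
            Affine(np.array([[1, 0, 0], [0, 1, 0], [0.1, 0, 1.0]]))

    def test_rigid_about_center_moves_content(self):
        c = (10.0, 20.0)
        g = Affine.rigid(90.0, (0, 0), center=c)
        np.testing.assert_allclose(g.apply(np.array(c)), c, atol=1e-12)
        np.testing.assert_allclose(g.apply(np.array([11.0, 20.0])), [10.0, 21.0],
                                   atol=1e-12)


# --- B-spline oracle: Cox-de Boor recursion, independent of scipy ----------


def _bspline_basis(knots, k, degree, x):
    if degree == 0:
        return 1.0 if knots[k] <= x < knots[k + 1] else 0.0
    out = 0.0
    d1 = knots[k + degree] - knots[k]
    if d1 > 0:
        out += (x - knots[k]) / d1 * _bspline_basis(knots, k, degree - 1, x)
    d2 = knots[k + degree + 1] - knots[k + 1]
    if d2 > 0:
        out += (knots[k + degree + 1] - x) / d2 * _bspline_basis(
            knots, k + 1, degree - 1, x)
    return out


def _brute_force_displace(t: BSplineTransform, point):
    x, y = point
    tx, ty = t.grid.knots(0), t.grid.knots(1)
    nx, ny = t.grid.size
    out = np.zeros(2)
    for k in range(nx):
        bx = _bspline_basis(tx, k, 3, x)
        if bx == 0.0:
            continue
        for l in range(ny):
            by = _bspline_basis(ty, l, 3, y)
            if by:
                out += t.coeffs[k, l] * bx * by
    return out


@pytest.fixture
def grid():
    return ControlGrid.for_image((40, 40), 10.0)


class TestBSpline:
    def test_zero_field_is_identity(self, grid):
        t = BSplineTransform.identity(grid)
        pts = np.array([[5.0, 7.0], [20.0, 30.0], [0.0, 39.0]])
        np.testing.assert_array_equal(t.apply(pts), pts)

    def test_uniform_field_shifts_everything(self, grid, rng):
        t = BSplineTransform(grid, np.broadcast_to([5.0, -3.0], (*grid.size, 2)))
        (xl, xh), (yl, yh) = grid.domain
        pts = np.column_stack([rng.uniform(max(xl, 0), min(xh, 39), 50),
                               rng.uniform(max(yl, 0), min(yh, 39), 50)])
        np.testing.assert_allclose(t.displace(pts),
                                   np.broadcast_to([5.0, -3.0], (50, 2)),
                                   atol=1e-12)

    def test_partition_of_unity(self, grid, rng):
        """Basis functions at any interior point sum to one."""
        ones = BSplineTransform(grid, np.broadcast_to([1.0, 1.0], (*grid.size, 2)))
        pts = np.column_stack([rng.uniform(0, 39, 100), rng.uniform(0, 39, 100)])
        np.testing.assert_allclose(ones.displace(pts), 1.0, atol=1e-12)

    def test_single_coefficient_matches_brute_force_oracle(self, grid, rng):
        c = np.zeros((*grid.size, 2))
        c[3, 2] = [4.0, -1.5]
        t = BSplineTransform(grid, c)
        pts = np.column_stack([rng.uniform(0, 39, 40), rng.uniform(0, 39, 40)])
        oracle = np.array([_brute_force_displace(t, p) for p in pts])
        np.testing.assert_allclose(t.displace(pts), oracle, atol=1e-10)

    def test_out_of_domain_rejected(self, grid):
        t = BSplineTransform.identity(grid)
        (xl, _), _ = grid.domain
        with pytest.raises(OutOfDomainError):
            t.displace([[xl - 5.0, 10.0]])

    def test_approx_invert_and_compose(self, grid, rng):
        c = rng.normal(size=(*grid.size, 2))
        t = BSplineTransform(grid, c)
        assert t.approx_invert().approx_invert() == t
        zero = t.approx_compose(t.approx_invert())
        np.testing.assert_array_equal(zero.coeffs, 0.0)

    def test_grid_mismatch_rejected(self, grid):
        other = ControlGrid.for_image((40, 40), 8.0)
        with pytest.raises(GridMismatchError):
            BSplineTransform.identity(grid).approx_compose(
                BSplineTransform.identity(other))

    def test_approx_compose_close_to_true_composition(self, grid, rng):
        """For small coefficients the control-polygon approximation of the
        composition stays within 1% of the grid spacing of the true function
        composition."""
        amp = 0.05 * grid.spacing[0]
        ca = rng.uniform(-amp, amp, size=(*grid.size, 2))
        cb = rng.uniform(-amp, amp, size=(*grid.size, 2))
        a = BSplineTransform(grid, ca)
        b = BSplineTransform(grid, cb)
        approx = a.approx_compose(b)
        gx, gy = np.meshgrid(np.linspace(2, 37, 12), np.linspace(2, 37, 12))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        true_comp = a.apply(b.apply(pts))
        err = np.abs(approx.apply(pts) - true_comp).max()
        assert err < 0.01 * grid.spacing[0]


class TestSerialization:
    @pytest.mark.parametrize("make", [
        lambda: Translation((1.25, -3.75)),
        lambda: Affine.rigid(17.0, (0.1234567890123, -9.87), center=(31.5, 31.5)),
        lambda: BSplineTransform(
            ControlGrid.for_image((20, 20), 5.0),
            np.random.default_rng(0).normal(size=(7, 7, 2))),
    ])
    def test_json_round_trip_bit_exact(self, make):
        t = make()
        doc = json.loads(json.dumps(transform_to_dict(t)))
        assert transform_from_dict(doc) == t

    def test_flat_coefficients_row_major(self):
        grid = ControlGrid.for_image((20, 20), 5.0)
        c = np.arange(2 * grid.size[0] * grid.size[1], dtype=float)
        t = BSplineTransform(grid, c)
        # k outer, l inner, 2-vector components innermost
        assert t.coeffs[0, 0, 0] == 0.0
        assert t.coeffs[0, 0, 1] == 1.0
        assert t.coeffs[0, 1, 0] == 2.0
        assert t.coeffs[1, 0, 0] == 2.0 * grid.size[1]
        np.testing.assert_array_equal(t.flat_coeffs, c)
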