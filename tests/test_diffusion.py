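"""Diffusion engine: update formulas, FTCS oracle equivalence, conservation,
stencil algebra, Gaussian limit, stability and kernel-width analytics."""

import numpy as np
import pytest

from tdrecon import (Affine, AlphaWarning, DiffusionConfig, NeighborTransforms,
                     StackTooShortError, Translation, accumulate,
                     diffuse_translations, fwhm_bw, fwhm_z, max_stable_alpha,
                     stability_amplification, sweep_matrix,
                     update_neighbor_transforms, update_slice_transforms,
                     wide_stencil_matrix)


def neighbor_transforms_from_positions(y):
    """Exact translation neighbour transforms f_ij = y_j - y_i."""
    n = len(y)
    prev = [None] + [Translation(y[i - 1] - y[i]) for i in range(1, n)]
    nxt = [Translation(y[i + 1] - y[i]) for i in range(n - 1)] + [None]
    return NeighborTransforms(prev, nxt)


class TestConfig:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            DiffusionConfig(alpha=0.55)
        with pytest.raises(ValueError):
            DiffusionConfig(alpha=0.0)
        with pytest.warns(AlphaWarning):
            DiffusionConfig(alpha=0.5)
        DiffusionConfig(alpha=0.45)  # default regime: no warning

    def test_sweeps_and_boundary(self):
        with pytest.raises(ValueError):
            DiffusionConfig(sweeps=0)
        with pytest.raises(ValueError):
            DiffusionConfig(boundary="dirichlet")


class TestSliceUpdate:
    def test_interior_update(self):
        nb = neighbor_transforms_from_positions(np.array([1.0, 0.0, 1.0]))
        upd = update_slice_transforms(nb, 0.45)
        # both neighbours sit +1 away from the centre slice
        np.testing.assert_allclose(upd[1].delta, [0.9], atol=1e-15)

    def test_boundary_doubled_term(self):
        nb = neighbor_transforms_from_positions(np.array([0.0, 1.0, 1.0]))
        upd = update_slice_transforms(nb, 0.45)
        np.testing.assert_allclose(upd[0].delta, [0.9], atol=1e-15)

    def test_identity_neighbors_give_identity_update_affine(self):
        eye = Affine.identity()
        nb = NeighborTransforms(prev=[None, eye, eye], next=[eye, eye, None])
        upd = update_slice_transforms(nb, 0.45)
        for u in upd:
            np.testing.assert_allclose(u.matrix, np.eye(3), atol=1e-12)

    def test_too_short_stack(self):
        with pytest.raises(StackTooShortError):
            NeighborTransforms(prev=[None], next=[None])


class TestNeighborUpdate:
    def test_translation_hand_example(self):
        # u_{i-1}=0.2, f_{i,i-1}=1.0, u_i=0.5 -> 0.2 + 1.0 - 0.5 = 0.7
        nb = NeighborTransforms(
            prev=[None, Translation(1.0)], next=[Translation(-1.0), None])
        upd = [Translation(0.2), Translation(0.5)]
        out = update_neighbor_transforms(nb, upd)
        np.testing.assert_allclose(out.prev[1].delta, [0.7], atol=1e-15)

    def test_identity_updates_leave_neighbors_unchanged(self):
        nb = neighbor_transforms_from_positions(np.array([0.0, 2.0, -1.0]))
        out = update_neighbor_transforms(nb, [Translation(0.0)] * 3)
        for a, b in zip(out.prev[1:], nb.prev[1:]):
            np.testing.assert_array_equal(a.delta, b.delta)

    def test_affine_sweep_matches_explicit_state_tracking(self):
        """Re-deriving the neighbour transforms from explicitly tracked
        per-slice states G_i' = U_i o G_i reproduces the transformation-space
        update exactly."""
        states = [Affine.rigid(5.0, (1.0, 0.5)),
                  Affine.rigid(-3.0, (0.0, 1.0)),
                  Affine.rigid(8.0, (-1.0, 0.2))]
        nb = NeighborTransforms(
            prev=[None] + [states[i - 1].compose(states[i].invert())
                           for i in range(1, 3)],
            next=[states[i + 1].compose(states[i].invert())
                  for i in range(2)] + [None])
        for _ in range(3):
            upd = update_slice_transforms(nb, 0.45)
            nb = update_neighbor_transforms(nb, upd)
            states = [u.compose(g) for u, g in zip(upd, states)]
            for i in range(1, 3):
                oracle = states[i - 1].compose(states[i].invert())
                np.testing.assert_allclose(nb.prev[i].matrix, oracle.matrix,
                                           atol=1e-10)
            for i in range(2):
                oracle = states[i + 1].compose(states[i].invert())
                np.testing.assert_allclose(nb.next[i].matrix, oracle.matrix,
                                           atol=1e-10)


class TestAccumulate:
    def test_translation_additive(self):
        tot = [Translation(0.0)]
        tot = accumulate(tot, [Translation(0.5)])
        tot = accumulate(tot, [Translation(-0.2)])
        np.testing.assert_allclose(tot[0].delta, [0.3], atol=1e-15)

    def test_affine_cancellation(self):
        f = Affine.rigid(12.0, (2.0, -1.0))
        tot = accumulate([Affine.identity()], [f])
        tot = accumulate(tot, [f.invert()])
        np.testing.assert_allclose(tot[0].matrix, np.eye(3), atol=1e-12)

    def test_type_mismatch(self):
        with pytest.raises(TypeError):
            accumulate([Translation(0.0)], [Affine.identity()])


class TestFTCSOracle:
    @pytest.mark.parametrize("n,sweeps,seed", [(5, 3, 0), (20, 50, 1), (50, 200, 2)])
    def test_translation_diffusion_equals_dense_ftcs(self, n, sweeps, seed):
        """y + accumulated updates == A^m y with A the Neumann FTCS matrix."""
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n, 1))
        prev = np.zeros_like(y)
        nxt = np.zeros_like(y)
        nxt[:-1] = y[1:] - y[:-1]
        prev[1:] = y[:-1] - y[1:]
        totals, _ = diffuse_translations(prev, nxt, 0.45, sweeps)
        oracle = np.linalg.matrix_power(sweep_matrix(n, 0.45), sweeps) @ y
        np.testing.assert_allclose(y + totals, oracle, atol=1e-12)

    def test_trapezoid_conservation_each_sweep(self):
        """The trapezoid-weighted sum (1/2, 1, ..., 1, 1/2) of translation
        updates vanishes every sweep: diffusion redistributes, never
        creates, displacement."""
        rng = np.random.default_rng(7)
        y = rng.normal(size=(12, 1))
        prev = np.zeros_like(y)
        nxt = np.zeros_like(y)
        nxt[:-1] = y[1:] - y[:-1]
        prev[1:] = y[:-1] - y[1:]
        w = np.ones(12)
        w[0] = w[-1] = 0.5
        last = {"tot": np.zeros_like(y)}

        def check(m, totals):
            upd = totals - last["tot"]
            last["tot"] = totals.copy()
            assert abs(float(w @ upd[:, 0])) < 1e-12

        diffuse_translations(prev, nxt, 0.45, 30, observer=check)

    def test_hand_example_updates(self):
        # phi = (0, 1, 0), alpha = 0.45 -> updates (0.9, -0.9, 0.9)
        y = np.array([[0.0], [1.0], [0.0]])
        prev = np.zeros_like(y)
        nxt = np.zeros_like(y)
        nxt[:-1] = y[1:] - y[:-1]
        prev[1:] = y[:-1] - y[1:]
        seen = {}

        def grab(m, totals):
            if m == 1:
                seen["upd"] = totals.copy()

        diffuse_translations(prev, nxt, 0.45, 1, observer=grab)
        np.testing.assert_allclose(seen["upd"][:, 0], [0.9, -0.9, 0.9],
                                   atol=1e-15)

    def test_convergence_to_common_value(self):
        """As m grows, all slices approach maximum alignment and the
        neighbour transforms approach identity."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=(15, 1))
        prev = np.zeros_like(y)
        nxt = np.zeros_like(y)
        nxt[:-1] = y[1:] - y[:-1]
        prev[1:] = y[:-1] - y[1:]
        totals, (pf, nf) = diffuse_translations(prev, nxt, 0.45, 5000)
        final = (y + totals)[:, 0]
        assert np.ptp(final) < 1e-8
        assert np.abs(nf[:-1]).max() < 1e-8


class TestStencilAlgebra:
    @pytest.mark.parametrize("n,d", [(10, 2), (30, 5), (30, 10), (8, 7)])
    def test_radius_equivalence(self, n, d):
        """d radius-1 sweeps equal one radius-d sweep with the induced
        stencil weights (matrix-power identity)."""
        a_pow = np.linalg.matrix_power(sweep_matrix(n, 0.45), d)
        wide = wide_stencil_matrix(n, 0.45, d)
        np.testing.assert_allclose(a_pow, wide, atol=1e-12)

    def test_gaussian_limit_of_impulse_response(self):
        """After M sweeps an interior unit impulse relaxes to a Gaussian of
        variance 2 alpha M (within 2% of the peak in L-infinity)."""
        alpha, m, n = 0.45, 100, 401
        imp = np.zeros(n)
        imp[n // 2] = 1.0
        prof = np.linalg.matrix_power(sweep_matrix(n, alpha), m) @ imp
        i = np.arange(n)
        var = 2.0 * alpha * m
        gauss = np.exp(-((i - n // 2) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        assert np.abs(prof - gauss).max() < 0.02 * gauss.max()


class TestAnalytics:
    def test_fwhm_z_closed_form(self):
        assert fwhm_z(0.45, 150, 20.0) == pytest.approx(273.6, abs=0.05)

    def test_fwhm_bw_closed_form(self):
        assert fwhm_bw(0.45, 42, 1.0) == pytest.approx(0.1915, abs=2e-4)

    def test_bandwidth_scales_inverse_sqrt_sweeps(self):
        assert fwhm_bw(0.45, 200) == pytest.approx(fwhm_bw(0.45, 100) / np.sqrt(2))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fwhm_z(0.45, 0, 1.0)
        with pytest.raises(ValueError):
            fwhm_bw(-0.1, 10, 1.0)

    @pytest.mark.parametrize("alpha,freq,gain", [
        (0.25, 0.5, 0.0),
        (0.5, 0.5, -1.0),
        (0.0, 0.3, 1.0),
    ])
    def test_mode_amplification(self, alpha, freq, gain):
        assert stability_amplification(alpha, freq) == pytest.approx(gain, abs=1e-12)

    def test_max_stable_alpha(self):
        assert max_stable_alpha() == 0.5
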