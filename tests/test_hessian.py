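"""Hessian assembly, symmetric-3×3 eigenanalysis, objectness measures, auto-c."""

import numpy as np
import pytest

import tubeness as tb
from tubeness.errors import (DegenerateInputError, InvalidInputError,
                             InvalidParameterError)
from tubeness.hessian import _magnitude_sort


def _field_from_diag(d1, d2, d3):
    z = np.zeros((1, 1, 1))
    return tb.HessianField(zz=z + d1, yy=z + d2, xx=z + d3,
                           zy=z, zx=z, yx=z, sigma=1.0)


def _field_from_matrices(M):
    return tb.HessianField(
        zz=M[:, 0, 0], yy=M[:, 1, 1], xx=M[:, 2, 2],
        zy=M[:, 0, 1], zx=M[:, 0, 2], yx=M[:, 1, 2], sigma=1.0,
    )


class TestHessianAtScale:
    def test_constant_volume_all_components_zero(self):
        v = tb.Volume(np.full((10, 10, 10), 4.2))
        f = tb.hessian_at_scale(v, tb.GaussianProbe(1.5))
        for comp in (f.zz, f.yy, f.xx, f.zy, f.zx, f.yx):
            np.testing.assert_allclose(comp, 0.0, atol=1e-10)

    def test_six_components_and_symmetry(self, random_volume):
        # the mixed component is computed once: Izy is the same grid for
        # both off-diagonal slots, and equals the (1,1,0) derivative
        probe = tb.GaussianProbe(1.5)
        f = tb.hessian_at_scale(random_volume, probe)
        direct = tb.gaussian_derivative(random_volume, probe, (1, 1, 0))
        np.testing.assert_array_equal(f.zy, direct.data)

    def test_tube_axis_from_smallest_eigenvector(self, straight_tube):
        probe = tb.GaussianProbe(3.0)
        f = tb.hessian_at_scale(straight_tube, probe)
        eig = tb.eigen_sym3(f, vectors=True)
        n = straight_tube.shape[0]
        sl = (slice(10, n - 10), n // 2, n // 2)
        # on the centerline the low-curvature direction is the tube axis (z)
        axis_dot = np.abs(eig.e1[sl][..., 0])
        assert axis_dot.min() > 0.99
        assert (eig.lam2[sl] < 0).all() and (eig.lam3[sl] < 0).all()


class TestEigenSym3:
    def test_diagonal_matrix_magnitude_order(self):
        eig = tb.eigen_sym3(_field_from_diag(-3.0, 1.0, -0.5))
        assert (eig.lam1[0, 0, 0], eig.lam2[0, 0, 0], eig.lam3[0, 0, 0]) == \
            (-0.5, 1.0, -3.0)

    def test_identity_matrix(self):
        eig = tb.eigen_sym3(_field_from_diag(1.0, 1.0, 1.0))
        assert (eig.lam1[0, 0, 0], eig.lam2[0, 0, 0], eig.lam3[0, 0, 0]) == \
            (1.0, 1.0, 1.0)

    def test_magnitude_tie_broken_by_signed_value(self):
        eig = tb.eigen_sym3(_field_from_diag(1.0, -1.0, 2.0))
        assert (eig.lam1[0, 0, 0], eig.lam2[0, 0, 0], eig.lam3[0, 0, 0]) == \
            (-1.0, 1.0, 2.0)
        stack = _magnitude_sort(np.array([3.0, -3.0, 0.5])[:, None])
        np.testing.assert_array_equal(stack[:, 0], [0.5, -3.0, 3.0])

    def test_matches_dense_solver_on_random_matrices(self, rng):
        M = rng.normal(size=(1000, 3, 3))
        M = (M + M.transpose(0, 2, 1)) / 2
        eig = tb.eigen_sym3(_field_from_matrices(M))
        ours = np.sort(np.stack([eig.lam1, eig.lam2, eig.lam3]), axis=0)
        ref = np.sort(np.linalg.eigvalsh(M), axis=1).T
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_eigenvector_residual(self, rng):
        M = rng.normal(size=(500, 3, 3))
        M = (M + M.transpose(0, 2, 1)) / 2
        eig = tb.eigen_sym3(_field_from_matrices(M), vectors=True)
        for lam, e in ((eig.lam1, eig.e1), (eig.lam2, eig.e2), (eig.lam3, eig.e3)):
            residual = np.einsum("nij,nj->ni", M, e) - lam[:, None] * e
            assert np.linalg.norm(residual, axis=1).max() < 1e-8

    def test_trace_identity(self, rng):
        M = rng.normal(size=(200, 3, 3))
        M = (M + M.transpose(0, 2, 1)) / 2
        eig = tb.eigen_sym3(_field_from_matrices(M))
        np.testing.assert_allclose(
            eig.lam1 + eig.lam2 + eig.lam3, np.trace(M, axis1=1, axis2=2),
            rtol=1e-8, atol=1e-10,
        )

    def test_non_finite_component_rejected(self):
        z = np.zeros((2, 2, 2))
        bad = z.copy()
        bad[1, 0, 1] = np.nan
        f = tb.HessianField(zz=bad, yy=z, xx=z, zy=z, zx=z, yx=z, sigma=1.0)
        with pytest.raises(InvalidInputError, match=r"\(1, 0, 1\)"):
            tb.eigen_sym3(f)


class TestFrangiVesselness:
    params = tb.ObjectnessParams(c=100.0, auto_c=False)

    def test_positive_lam2_or_lam3_scores_zero(self):
        assert tb.frangi_vesselness((0.1, 2.0, -5.0), self.params) == 0.0
        assert tb.frangi_vesselness((0.1, -2.0, 5.0), self.params) == 0.0

    def test_all_zero_eigenvalues_score_zero(self):
        assert tb.frangi_vesselness((0.0, 0.0, 0.0), self.params) == 0.0

    def test_ideal_tube_hand_value(self):
        # Ra=1, Rb=0, S^2/2c^2 = 1: (1-e^-2)*1*(1-e^-1)
        score = tb.frangi_vesselness((0.0, -100.0, -100.0), self.params)
        assert score == pytest.approx((1 - np.exp(-2)) * (1 - np.exp(-1)), rel=1e-12)

    def test_dark_polarity_flips_sign_convention(self):
        dark = tb.ObjectnessParams(c=100.0, auto_c=False, polarity="dark")
        assert tb.frangi_vesselness((0.0, 100.0, 100.0), dark) == \
            tb.frangi_vesselness((0.0, -100.0, -100.0), self.params)
        assert tb.frangi_vesselness((0.0, -100.0, -100.0), dark) == 0.0

    def test_score_bounded_in_unit_interval(self, rng):
        lams = _magnitude_sort(rng.normal(scale=50, size=(3, 4000)))
        s = tb.frangi_vesselness((lams[0], lams[1], lams[2]), self.params)
        assert (s >= 0).all() and (s <= 1).all()

    def test_monotone_in_structure_energy(self):
        # fixed ratios (ideal tube), growing |eigenvalues| = growing S
        ks = np.linspace(1, 500, 40)
        scores = [tb.frangi_vesselness((0.0, -k, -k), self.params) for k in ks]
        assert np.all(np.diff(scores) >= 0)

    def test_c_limits(self):
        eig = (0.0, -10.0, -20.0)
        big_c = tb.ObjectnessParams(c=1e9, auto_c=False)
        assert tb.frangi_vesselness(eig, big_c) == pytest.approx(0.0, abs=1e-12)
        small_c = tb.ObjectnessParams(c=1e-9, auto_c=False)
        two_factor = (1 - np.exp(-(0.5**2) / 0.5)) * 1.0  # Ra=1/2, Rb=0
        assert tb.frangi_vesselness(eig, small_c) == \
            pytest.approx(two_factor, rel=1e-10)

    def test_ratios_invariant_under_intensity_scaling(self):
        # scaling eigenvalues and c together by k leaves the score unchanged
        eig = (-0.5, -4.0, -9.0)
        k = 37.0
        scaled = tuple(k * v for v in eig)
        p_scaled = tb.ObjectnessParams(c=k * 100.0, auto_c=False)
        assert tb.frangi_vesselness(scaled, p_scaled) == \
            pytest.approx(tb.frangi_vesselness(eig, self.params), rel=1e-12)

    def test_missing_c_rejected(self):
        with pytest.raises(InvalidParameterError):
            tb.frangi_vesselness((0.0, -1.0, -2.0),
                                 tb.ObjectnessParams(auto_c=False))

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            tb.ObjectnessParams(a=0.0)
        with pytest.raises(InvalidParameterError):
            tb.ObjectnessParams(c=-1.0)
        with pytest.raises(InvalidParameterError):
            tb.ObjectnessParams(alpha1=2.0, alpha2=0.5)


class TestSatoMeasure:
    params = tb.ObjectnessParams(c=1.0, auto_c=False, measure="sato")

    def test_zero_lambda_c_scores_zero(self):
        assert tb.sato_measure(0.0, 0.0, 0.0, self.params) == 0.0

    def test_ideal_line_scores_one(self):
        assert tb.sato_measure(0.0, -4.0, -4.0, self.params) == 1.0

    def test_negative_lam1_branch_hand_value(self):
        # lam_c = 2, alpha1 = 0.5: exp(-1 / (2*(0.5*2)^2)) = exp(-1/2)
        assert tb.sato_measure(-1.0, -2.0, -2.0, self.params) == \
            pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_positive_lam1_branch_uses_alpha2(self):
        # lam_c = 2, alpha2 = 2: exp(-1 / (2*(2*2)^2)) = exp(-1/32)
        assert tb.sato_measure(1.0, -2.0, -2.0, self.params) == \
            pytest.approx(np.exp(-1 / 32), rel=1e-12)


class TestLaplacian:
    def test_constant_volume_zero_field(self):
        v = tb.Volume(np.full((8, 8, 8), 2.0))
        out = tb.laplacian_field(v, tb.GaussianProbe(1.5))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_equals_hessian_trace(self, random_volume):
        probe = tb.GaussianProbe(2.0)
        lap = tb.laplacian_field(random_volume, probe)
        f = tb.hessian_at_scale(random_volume, probe)
        np.testing.assert_allclose(lap.data, f.trace(), atol=1e-12)

    def test_equals_eigenvalue_sum(self, random_volume):
        probe = tb.GaussianProbe(2.0)
        lap = tb.laplacian_field(random_volume, probe)
        eig = tb.eigen_sym3(tb.hessian_at_scale(random_volume, probe))
        np.testing.assert_allclose(
            lap.data, eig.lam1 + eig.lam2 + eig.lam3, atol=1e-8
        )


class TestAutoC:
    def test_definition_max_laplacian_over_divisor(self, straight_tube):
        lap_max = tb.image_laplacian(straight_tube).data.max()
        assert tb.auto_c(straight_tube) == pytest.approx(lap_max / 10, rel=1e-12)
        assert tb.auto_c(straight_tube, divisor=4.0) == \
            pytest.approx(lap_max / 4, rel=1e-12)

    @pytest.mark.parametrize("mode", ["image", "multiscale", "single"])
    def test_intensity_scaling_equivariance(self, straight_tube, mode):
        k = 7.5
        scaled = straight_tube.with_data(k * straight_tube.data)
        scales = [1.0, 2.0, 4.0]
        c1 = tb.auto_c(straight_tube, scales, mode=mode)
        c2 = tb.auto_c(scaled, scales, mode=mode)
        assert c2 == pytest.approx(k * c1, rel=1e-10)

    def test_translation_invariance(self):
        n = 40
        tube = tb.TubeSpec(centerline=[(0, 14, 14), (n - 1, 14, 14)],
                           sigma_obj=2.0, amplitude=1.0)
        v = tb.make_tube(tube, (n, n, n))
        shifted = v.with_data(np.roll(v.data, (0, 6, 6), axis=(0, 1, 2)))
        assert tb.auto_c(shifted) == pytest.approx(tb.auto_c(v), rel=1e-9)

    def test_multiscale_mode_tracks_scale_list(self, straight_tube):
        c_small = tb.auto_c(straight_tube, [1.0], mode="multiscale")
        c_multi = tb.auto_c(straight_tube, [1.0, 3.0], mode="multiscale")
        assert c_multi >= c_small
        spec = tb.ScaleSpec(1.0, 3.0, 2)
        assert tb.auto_c(straight_tube, spec, mode="multiscale") == \
            pytest.approx(c_multi, rel=1e-12)
        assert tb.auto_c(straight_tube, spec, mode="single") == \
            pytest.approx(c_small, rel=1e-12)

    def test_constant_volume_is_degenerate(self):
        v = tb.Volume(np.full((10, 10, 10), 5.0))
        with pytest.raises(DegenerateInputError):
            tb.auto_c(v)

    def test_invalid_arguments(self, straight_tube):
        with pytest.raises(InvalidParameterError):
            tb.auto_c(straight_tube, divisor=0.0)
        with pytest.raises(InvalidParameterError):
            tb.auto_c(straight_tube, mode="bogus")
        with pytest.raises(InvalidParameterError):
            tb.auto_c(straight_tube, None, mode="multiscale")
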