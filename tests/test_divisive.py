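"""Divisive normalization: forward, Jacobians, Gaussian kernels, inverse."""

import numpy as np
import pytest

from conftest import grid_kernel_spec, random_dn_params, random_signed
from lnlcascade.calculus import fd_oracle
from lnlcascade.divisive import (
    DivNormParams,
    GaussianKernelSpec,
    build_gaussian_H,
    dn_forward,
    dn_inverse,
    dn_invertibility_margin,
    dn_jacobian_kernel_params,
    dn_jacobian_params,
    dn_jacobian_stimulus,
    gaussian_H_dc,
    gaussian_H_dsigma,
)

SCALAR = DivNormParams(gamma=1.0, b=np.array([1.0]), H=np.array([[1.0]]))


class TestForward:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(dn_forward(np.zeros(3),
                                                 random_dn_params(np.random.default_rng(0), 3)),
                                      np.zeros(3))

    def test_scalar_example(self):
        np.testing.assert_allclose(dn_forward(np.array([2.0]), SCALAR), [2 / 3])

    def test_no_interaction_unit_denominator_is_identity(self):
        p = DivNormParams(1.0, np.ones(4), np.zeros((4, 4)))
        y = np.array([-3.0, 0.5, 7.0, 0.0])
        np.testing.assert_allclose(dn_forward(y, p), y)

    def test_sign_equivariance(self, rng):
        p = random_dn_params(rng, 6)
        y = random_signed(rng, 6)
        np.testing.assert_allclose(dn_forward(-y, p), -dn_forward(y, p), atol=1e-14)

    def test_rejects_nonpositive_b(self):
        with pytest.raises(ValueError):
            DivNormParams(1.0, np.array([0.0]), np.array([[1.0]]))


class TestStimulusJacobian:
    def test_scalar_closed_form(self):
        # d/dy [y/(1+y)] = 1/(1+y)^2 at y=2
        J = dn_jacobian_stimulus(np.array([2.0]), SCALAR)
        np.testing.assert_allclose(J, [[1 / 9]])

    def test_diagonal_when_H_is_identity(self, rng):
        # self-inhibition only: x_k = y_k/(b_k+|y_k|), slope b_k/(b_k+|y_k|)^2
        d = 5
        p = DivNormParams(1.0, rng.uniform(0.5, 2, d), np.eye(d))
        y = random_signed(rng, d)
        J = dn_jacobian_stimulus(y, p)
        np.testing.assert_allclose(J, np.diag(np.diag(J)))
        np.testing.assert_allclose(np.diag(J), p.b / (p.b + np.abs(y)) ** 2)

    def test_diagonal_when_H_zero(self, rng):
        # no interaction at all: x = y/b, constant slope 1/b
        d = 5
        p = DivNormParams(1.0, rng.uniform(0.5, 2, d), np.zeros((d, d)))
        J = dn_jacobian_stimulus(random_signed(rng, d), p)
        np.testing.assert_allclose(J, np.diag(1 / p.b))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 8))
        p = random_dn_params(rng, d)
        y = random_signed(rng, d)
        J = dn_jacobian_stimulus(y, p)
        Jfd = fd_oracle(lambda z: dn_forward(z, p), y)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-6


class TestParamJacobians:
    def test_scalar_closed_forms(self):
        g = dn_jacobian_params(np.array([2.0]), SCALAR)
        np.testing.assert_allclose(g["b"], [[-2 / 9]])
        np.testing.assert_allclose(g["gamma"], [[2 * np.log(2) / 9]])
        np.testing.assert_allclose(g["H"], [[-4 / 9]])

    def test_zero_component_rejected_for_gamma(self):
        with pytest.raises(ValueError, match="log"):
            dn_jacobian_params(np.array([0.0, 1.0]),
                               random_dn_params(np.random.default_rng(0), 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_match_finite_differences(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = int(rng.integers(2, 6))
        p = random_dn_params(rng, d)
        y = random_signed(rng, d)
        g = dn_jacobian_params(y, p)

        def of_gamma(v):
            return dn_forward(y, DivNormParams(float(v[0]), p.b, p.H))

        def of_b(bv):
            return dn_forward(y, DivNormParams(p.gamma, bv, p.H))

        def of_H(hv):
            return dn_forward(y, DivNormParams(p.gamma, p.b, hv.reshape(d, d)))

        for ana, fd in [
            (g["gamma"], fd_oracle(of_gamma, np.array([p.gamma]))),
            (g["b"], fd_oracle(of_b, p.b)),
            (g["H"], fd_oracle(of_H, p.H.ravel())),
        ]:
            assert np.max(np.abs(ana - fd)) / np.max(np.abs(fd)) < 1e-6


class TestGaussianKernel:
    def test_single_sensor_subbands_make_H_diagonal(self):
        spec = GaussianKernelSpec(
            positions=np.zeros((3, 2)), subband=np.arange(3),
            sigma=np.full(3, 0.1), c=np.full(3, 0.5), dp=0.01,
        )
        H = build_gaussian_H(spec)
        np.testing.assert_allclose(H, np.diag(np.full(3, 0.5 * 0.01 / (2 * np.pi * 0.01))))

    def test_cross_subband_entries_exactly_zero(self, rng):
        spec = grid_kernel_spec(rng)
        spec.subband = np.repeat([0, 1, 2], 3)
        H = build_gaussian_H(spec)
        mask = spec.subband[:, None] != spec.subband[None, :]
        assert np.all(H[mask] == 0)

    def test_fine_grid_row_pool_approaches_c(self):
        # σ much larger than the grid step: the discrete pool integrates the
        # Gaussian, so the row sum tends to c (checked at the grid centre)
        n, step, sigma = 61, 0.01, 0.07
        pos = np.array([[i, j] for i in range(n) for j in range(n)], float) * step
        spec = GaussianKernelSpec(
            positions=pos, subband=np.zeros(n * n, int),
            sigma=np.full(n * n, sigma), c=np.full(n * n, 0.4), dp=step**2,
        )
        H = build_gaussian_H(spec)
        centre = (n * n) // 2
        assert abs(H[centre].sum() - 0.4) / 0.4 < 0.01

    def test_dH_dc_is_H_over_c(self, rng):
        spec = grid_kernel_spec(rng)
        np.testing.assert_allclose(
            gaussian_H_dc(spec), build_gaussian_H(spec) / spec.c[:, None]
        )

    def test_dH_dsigma_matches_finite_differences(self, rng):
        spec = grid_kernel_spec(rng)
        d = spec.d
        F = gaussian_H_dsigma(spec)

        def H_of(sv):
            s2 = GaussianKernelSpec(spec.positions, spec.subband, sv, spec.c, spec.dp)
            return build_gaussian_H(s2).ravel()

        fd = fd_oracle(H_of, spec.sigma)
        ana = np.zeros((d * d, d))
        for k in range(d):
            ana[k * d : (k + 1) * d, k] = F[k]
        assert np.max(np.abs(ana - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            GaussianKernelSpec(
                positions=np.zeros((1, 2)), subband=np.zeros(1, int),
                sigma=np.array([0.0]), c=np.array([1.0]), dp=0.01,
            )


class TestKernelParamJacobians:
    @pytest.mark.parametrize("shared", [False, True])
    def test_sigma_and_c_match_finite_differences(self, rng, shared):
        spec = grid_kernel_spec(rng, shared=shared)
        d = spec.d
        p = DivNormParams(gamma=0.8, b=rng.uniform(0.5, 1.5, d), kernel_spec=spec)
        y = random_signed(rng, d)
        grads = dn_jacobian_kernel_params(y, p)

        def resp(sigma=None, c=None):
            s2 = GaussianKernelSpec(
                spec.positions, spec.subband,
                spec.sigma if sigma is None else sigma,
                spec.c if c is None else c, spec.dp,
                structure_sigma=spec.structure_sigma, structure_c=spec.structure_c,
            )
            return dn_forward(y, DivNormParams(p.gamma, p.b, kernel_spec=s2))

        fd_sigma = fd_oracle(lambda v: resp(sigma=v), spec.sigma)
        fd_c = fd_oracle(lambda v: resp(c=v), spec.c)
        assert np.max(np.abs(grads["sigma"] - fd_sigma)) / np.max(np.abs(fd_sigma)) < 1e-6
        assert np.max(np.abs(grads["c"] - fd_c)) / np.max(np.abs(fd_c)) < 1e-6

    def test_structured_column_is_sum_of_per_sensor_columns(self, rng):
        # one shared σ: the structured gradient pools the per-sensor ones
        spec_ind = grid_kernel_spec(rng)
        spec_shared = GaussianKernelSpec(
            spec_ind.positions, spec_ind.subband,
            sigma=np.array([0.18]), c=spec_ind.c, dp=spec_ind.dp,
            structure_sigma=np.ones((spec_ind.d, 1)),
        )
        spec_ind.sigma = np.full(spec_ind.d, 0.18)
        d = spec_ind.d
        b = rng.uniform(0.5, 1.5, d)
        y = random_signed(rng, d)
        g_ind = dn_jacobian_kernel_params(y, DivNormParams(0.8, b, kernel_spec=spec_ind))
        g_sh = dn_jacobian_kernel_params(y, DivNormParams(0.8, b, kernel_spec=spec_shared))
        np.testing.assert_allclose(
            g_sh["sigma"].ravel(), g_ind["sigma"].sum(axis=1), rtol=1e-12
        )

    def test_missing_spec_rejected(self, rng):
        p = random_dn_params(rng, 3)
        with pytest.raises(ValueError):
            dn_jacobian_kernel_params(np.ones(3), p)


class TestInverse:
    def test_scalar_example(self):
        np.testing.assert_allclose(dn_inverse(np.array([2 / 3]), SCALAR), [2.0])

    def test_diagonal_closed_form_when_H_zero(self, rng):
        d = 4
        p = DivNormParams(0.7, rng.uniform(0.5, 2, d), np.zeros((d, d)))
        x = rng.uniform(-0.8, 0.8, d)
        expected = np.sign(x) * (p.b * np.abs(x)) ** (1 / 0.7)
        np.testing.assert_allclose(dn_inverse(x, p), expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = int(rng.integers(2, 10))
        p = random_dn_params(rng, d)
        y = random_signed(rng, d)
        x = dn_forward(y, p)
        assert dn_invertibility_margin(x, p) < 0.95
        np.testing.assert_allclose(dn_inverse(x, p), y, atol=1e-9)

    def test_series_converges_monotonically_to_direct(self, rng):
        p = random_dn_params(rng, 5)
        y = random_signed(rng, 5)
        x = dn_forward(y, p)
        direct = dn_inverse(x, p)
        errs = []
        for order in [1, 3, 6, 12, 25]:
            approx = dn_inverse(x, p, method="series", order=order,
                                residual_tol=np.inf)
            errs.append(np.linalg.norm(approx - direct))
        assert all(e2 <= e1 + 1e-14 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < 1e-8

    def test_margin_and_invertibility_agree(self, rng):
        # radius < 1 iff the inverse solve succeeds (property sweep)
        for _ in range(10):
            d = 4
            scale = rng.uniform(0.2, 3.0)
            H = np.full((d, d), scale / d)
            p = DivNormParams(1.0, np.full(d, 0.5), H)
            x = rng.uniform(0.3, 0.9, d)
            radius = dn_invertibility_margin(x, p)
            if radius >= 1:
                with pytest.raises(np.linalg.LinAlgError):
                    dn_inverse(x, p)
            else:
                dn_inverse(x, p)  # must not raise

    def test_H_zero_radius_zero(self):
        p = DivNormParams(1.0, np.ones(3), np.zeros((3, 3)))
        assert dn_invertibility_margin(np.ones(3), p) == 0.0

    def test_scalar_radius(self):
        p = DivNormParams(1.0, np.array([1.0]), np.array([[1.0]]))
        assert dn_invertibility_margin(np.array([0.5]), p) == pytest.approx(0.5)
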