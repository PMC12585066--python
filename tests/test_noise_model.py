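"""Unit and property tests for the count-distribution model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scmospia import (
    CameraParams,
    PixelModel,
    QuadratureConfig,
    cf_photoelectrons,
    cf_quantization,
    cf_read_noise,
    cf_total,
    pmf,
    sum_count_pvalue,
    tl_quantile,
    tl_variance,
)


class TestTLQuantile:
    @pytest.mark.parametrize("u, shape, expected", [
        (0.5, 0.3, 0.0),                 # antisymmetry at the median
        (0.75, 1.0, 0.5),                # shape 1: Q = 2u - 1
        (0.9, 0.0, np.log(9.0)),         # logistic branch
    ])
    def test_closed_forms(self, u, shape, expected):
        assert tl_quantile(u, shape) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, u):
        with pytest.raises(ValueError):
            tl_quantile(u, 0.1)

    def test_continuity_at_zero_shape(self):
        # the generic branch converges to the logistic one
        assert tl_quantile(0.9, 1e-9) == pytest.approx(np.log(9.0), rel=1e-6)
        assert tl_quantile(0.9, 1e-4) == pytest.approx(np.log(9.0), rel=1e-3)

    @given(u=st.floats(0.01, 0.99), shape=st.floats(-0.45, 1.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_antisymmetry(self, u, shape):
        assert tl_quantile(u, shape) == pytest.approx(
            -tl_quantile(1.0 - u, shape), abs=1e-9)

    @given(shape=st.floats(-0.45, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_u(self, shape):
        u = np.linspace(0.01, 0.99, 50)
        q = tl_quantile(u, shape)
        assert np.all(np.diff(q) > 0)


class TestTLVariance:
    def test_shape_one_is_uniform(self):
        # shape 1 gives uniform on [-1, 1], variance 1/3
        assert tl_variance(1.0, 1.0) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_shape_zero_is_logistic(self):
        assert tl_variance(0.0, 2.0) == pytest.approx(4.0 * np.pi**2 / 3.0, rel=1e-9)

    def test_reference_read_noise_variance(self):
        # frozen Monte-Carlo oracle: var of 1.310 * Q(U; 0.055) over 1e7
        # seeded uniform draws gave 4.6974
        assert tl_variance(0.055, 1.310) == pytest.approx(4.6974, rel=0.01)

    def test_sampling_oracle_near_gaussian_shape(self):
        rng = np.random.default_rng(42)
        draws = tl_quantile(rng.uniform(size=10**6), 0.14)
        assert tl_variance(0.14, 1.0) == pytest.approx(np.var(draws), rel=0.01)

    @pytest.mark.parametrize("shape", [-0.5, -0.7])
    def test_infinite_variance_domain_error(self, shape):
        with pytest.raises(ValueError):
            tl_variance(shape, 1.0)


class TestCharacteristicFunctions:
    def test_photoelectron_cf_closed_forms(self):
        assert cf_photoelectrons(0.0, 3.7, 0.81) == pytest.approx(1.0)
        assert cf_photoelectrons(1.3, 0.0, 0.81) == pytest.approx(1.0)
        assert cf_photoelectrons(np.pi, 2.0, 1.0) == pytest.approx(np.exp(-4.0))

    def test_read_noise_cf_normalization_and_zero_scale(self):
        assert cf_read_noise(0.0, 0.055, 1.31) == pytest.approx(1.0, abs=1e-8)
        assert cf_read_noise(2.0, 0.3, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [0.25, 0.5, 1.0, 2.0, 3.0])
    def test_read_noise_cf_uniform_oracle(self, k):
        # shape 1 read noise is uniform on [-scale, scale]: CF sin(ks)/(ks)
        approx = cf_read_noise(k, 1.0, 1.0, QuadratureConfig(n_r=2001))
        assert approx == pytest.approx(np.sin(k) / k, abs=1e-6)

    def test_quantization_cf(self):
        assert cf_quantization(0.0) == 1.0
        assert cf_quantization(2 * np.pi) == pytest.approx(0.0, abs=1e-12)
        assert cf_quantization(np.pi) == pytest.approx(2.0 / np.pi, rel=1e-12)

    def test_total_cf_modulus_bound_and_pure_shift(self, chip):
        k = np.linspace(0.0, np.pi, 301)
        phi = cf_total(k, PixelModel(chip, 37.0))
        assert np.abs(phi[0] - 1.0) < 1e-8
        assert np.all(np.abs(phi) <= 1.0 + 1e-6)
        # lam = 0, no read noise: only quantization and the offset phase remain
        shift = CameraParams(gain=1.0, tl_shape=0.1, tl_scale=0.0, offset=5.0)
        phi_s = cf_total(k[1:], PixelModel(shift, 0.0))
        expected = np.sinc(k[1:] / (2 * np.pi)) * np.exp(5j * k[1:])
        np.testing.assert_allclose(phi_s, expected, atol=1e-12)


class TestPMF:
    def test_poisson_limit(self, poisson_chip):
        # unit gain, no read noise: counts are exactly Poisson; lambda large
        # enough that dropping the CF aliases is negligible
        dist = pmf(PixelModel(poisson_chip, 50.0))
        tv = 0.5 * np.sum(np.abs(dist.pmf - stats.poisson.pmf(dist.support, 50.0)))
        assert tv < 1e-3

    def test_poisson_low_lambda_frozen_accuracy(self, poisson_chip):
        # at lambda = 5 the 2pi-periodic Poisson CF factor makes the dropped
        # aliases visible; the measured total-variation error of the
        # inversion is 4.1e-3 (frozen), dominated by the sinc-factor tail
        dist = pmf(PixelModel(poisson_chip, 5.0))
        tv = 0.5 * np.sum(np.abs(dist.pmf - stats.poisson.pmf(dist.support, 5.0)))
        assert tv < 5e-3
        assert dist.mean() == pytest.approx(5.0, abs=0.01)

    def test_degenerate_count_is_concentrated(self):
        params = CameraParams(gain=1.0, tl_shape=0.1, tl_scale=0.0, offset=100.0)
        with pytest.warns(UserWarning):
            dist = pmf(PixelModel(params, 0.0))
        assert dist.support[np.argmax(dist.pmf)] == 100
        assert dist.prob(100) > 0.8

    @pytest.mark.parametrize("lam", [1.0, 10.0, 100.0])
    def test_normalization_and_moment_identities(self, chip, lam):
        model = PixelModel(chip, lam)
        dist = pmf(model)
        assert abs(dist.total_mass - 1.0) < 1e-4
        assert dist.mean() == pytest.approx(model.mean(), rel=0.01)
        assert dist.var() == pytest.approx(model.variance(), rel=0.01)

    def test_reference_model_moments(self, chip):
        # calibrated camera at lambda 102.6: mean g*lam + offset = 183.2,
        # variance g^2*lam + s2_TL + 1/12
        dist = pmf(PixelModel(chip, 102.6))
        assert dist.mean() == pytest.approx(183.206, abs=0.5)
        assert dist.var() == pytest.approx(
            0.81**2 * 102.6 + tl_variance(0.055, 1.310) + 1 / 12, rel=0.02)

    def test_cdf_is_cumsum_and_monotone(self, chip):
        dist = pmf(PixelModel(chip, 10.0))
        np.testing.assert_allclose(dist.cdf, np.cumsum(dist.pmf), rtol=1e-12)
        assert np.all(np.diff(dist.cdf) >= 0)
        assert dist.cdf[-1] <= 1.0 + 1e-9

    def test_non_integer_support_rejected(self, chip):
        with pytest.raises(ValueError):
            pmf(PixelModel(chip, 5.0), support=np.linspace(0, 10, 11))

    def test_narrow_support_flagged(self, chip):
        with pytest.warns(UserWarning):
            dist = pmf(PixelModel(chip, 100.0), support=np.arange(180, 186))
        assert not dist.well_normalized

    def test_near_gaussian_shape(self):
        # shape 0.14 approximates a Gaussian: standardized quantiles
        # correlate with normal quantiles at > 0.999
        u = (np.arange(1, 10**4 + 1) - 0.5) / 10**4
        q_tl = tl_quantile(u, 0.14)
        q_n = stats.norm.ppf(u)
        rho = np.corrcoef(q_tl, q_n)[0, 1]
        assert rho > 0.999


class TestSumCountPvalue:
    def test_single_pixel_matches_cdf(self, chip):
        model = PixelModel(chip, 102.6)
        dist = pmf(model)
        for total in [190, 200, 210]:
            expected = 1.0 - dist.cdf_at(total - 1)
            assert sum_count_pvalue(total, 1, model) == pytest.approx(
                expected, abs=1e-6)

    def test_two_pixel_convolution_oracle(self, chip):
        model = PixelModel(chip, 3.0)
        dist = pmf(model)
        conv = np.convolve(dist.pmf, dist.pmf)
        support2 = np.arange(2 * dist.support[0], 2 * dist.support[-1] + 1)
        sf = 1.0 - np.cumsum(conv)
        for total in [204, 208, 212]:
            idx = total - 1 - support2[0]
            assert sum_count_pvalue(total, 2, model) == pytest.approx(
                sf[idx], abs=1e-3)

    def test_monotone_in_total(self, chip):
        model = PixelModel(chip, 102.6)
        ps = [sum_count_pvalue(t, 4, model) for t in range(700, 800, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_normal_regime_continuity(self, chip):
        # the CF-power route and the moment-matched normal tail agree
        # near the switch-over region size
        model = PixelModel(chip, 50.0)
        total = int(64 * model.mean() + 3 * np.sqrt(64 * model.variance()))
        p_cf = sum_count_pvalue(total, 64, model)
        p_n = sum_count_pvalue(int(total * 65 / 64), 65, model)
        assert p_n == pytest.approx(p_cf, rel=0.25)

    def test_requires_positive_region(self, chip):
        with pytest.raises(ValueError):
            sum_count_pvalue(100, 0, PixelModel(chip, 1.0))


class TestCameraParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"gain": 0.0}, {"gain": -1.0}, {"tl_shape": -0.5},
        {"tl_scale": -0.1}, {"offset": -5.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = {"gain": 1.0, "tl_shape": 0.1, "tl_scale": 1.0, "offset": 100.0}
        with pytest.raises(ValueError):
            CameraParams(**{**base, **kwargs})

    def test_roundtrip_dict(self, chip):
        assert CameraParams.from_dict(chip.to_dict()) == chip
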