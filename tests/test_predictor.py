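import math

import numpy as np
import pytest

from neuroindex.exceptions import DataError, DomainError, GridError, ParameterError
from neuroindex.predictor import (
    METHOD_MODEL,
    METHOD_PSD,
    ModelParams,
    SpectralModelFit,
    combine_predictors,
    compute_predictor,
    fit_psd_model,
    model_psd,
    power_law,
)
from neuroindex.synth import sample_model_psd

SQRT_2PI = math.sqrt(2 * math.pi)
FIT_GRID = np.arange(2.0, 35.01, 0.25)


class TestModelPsd:
    def test_degenerate_constant(self):
        p = ModelParams(k1=3.0, a2=0.0, k2=-1.0, a3=0.0, mu=10.0, sigma=1.0)
        np.testing.assert_allclose(model_psd(FIT_GRID, p), 3.0)

    def test_gaussian_maximum_closed_form(self):
        p = ModelParams(k1=1.0, a2=50.0, k2=-1.2, a3=8.0, mu=10.0, sigma=1.0)
        at_mu = model_psd(np.array([10.0]), p)[0]
        pl_at_mu = power_law(np.array([10.0]), p)[0]
        assert at_mu - pl_at_mu == pytest.approx(8.0 / SQRT_2PI, rel=1e-12)

    def test_hand_arithmetic_at_ten_hz(self):
        # 1 + 50 * 10**(-1.2) = 4.154845...
        p = ModelParams(k1=1.0, a2=50.0, k2=-1.2, a3=0.0, mu=10.0, sigma=1.0)
        assert model_psd(np.array([10.0]), p)[0] == pytest.approx(
            1.0 + 50.0 * 10 ** (-1.2), rel=1e-12
        )

    def test_nonpositive_frequency_rejected(self):
        p = ModelParams(k1=0.0, a2=1.0, k2=-1.0, a3=0.0, mu=10.0, sigma=1.0)
        with pytest.raises(DomainError):
            model_psd(np.array([0.0, 1.0]), p)

    def test_beta_peak_term(self):
        p = ModelParams(1.0, 0.0, -1.0, 0.0, 10.0, 1.0, a3b=4.0, mub=20.0, sigmab=2.0)
        at_mub = model_psd(np.array([20.0]), p)[0]
        assert at_mub == pytest.approx(1.0 + 4.0 / (2.0 * SQRT_2PI), rel=1e-12)


class TestModelParamsInvariants:
    def test_sigma_positive(self):
        with pytest.raises(DomainError):
            ModelParams(0.0, 1.0, -1.0, 1.0, 10.0, 0.0)

    def test_k2_nonpositive(self):
        with pytest.raises(DomainError):
            ModelParams(0.0, 1.0, 0.5, 1.0, 10.0, 1.0)

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(DomainError):
            ModelParams(-1.0, 1.0, -1.0, 1.0, 10.0, 1.0)

    def test_beta_center_must_exceed_alpha(self):
        with pytest.raises(DomainError):
            ModelParams(0.0, 1.0, -1.0, 1.0, 10.0, 1.0, a3b=1.0, mub=9.0, sigmab=1.0)

    def test_partial_second_peak_rejected(self):
        with pytest.raises(DomainError):
            ModelParams(0.0, 1.0, -1.0, 1.0, 10.0, 1.0, a3b=1.0)


class TestFitPsdModel:
    def test_noiseless_single_peak_recovery(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        assert fit.converged
        truth = dict(k1=1.0, a2=50.0, k2=-1.2, a3=8.0, mu=10.0, sigma=1.0)
        for name, expected in truth.items():
            got = getattr(fit.params, name)
            assert abs(got - expected) / abs(expected) < 1e-3, (name, got)

    def test_pure_power_law_gives_negligible_peak(self):
        p = ModelParams(1.0, 50.0, -1.2, 0.0, 10.0, 1.0)
        psd = sample_model_psd(p, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        assert fit.params.a3 <= 1e-6 * np.max(psd.power)
        np.testing.assert_allclose(fit.fitted, fit.power_law, atol=1e-6 * np.max(psd.power))

    def test_two_bumps_recovered(self):
        p = ModelParams(1.0, 50.0, -1.2, 8.0, 10.0, 1.0, a3b=4.0, mub=20.0, sigmab=1.5)
        psd = sample_model_psd(p, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=True)
        assert fit.converged
        assert fit.params.mu == pytest.approx(10.0, abs=0.25)
        assert fit.params.mub == pytest.approx(20.0, abs=0.25)

    def test_iaf_initialization_respected(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        fit = fit_psd_model(psd, "C3", iaf_hz=10.0, two_peaks=False)
        assert fit.converged
        assert fit.params.mu == pytest.approx(10.0, abs=1e-3)

    def test_zero_psd_raises(self, welch_grid):
        from tests.conftest import make_psd

        psd = make_psd({"C3": np.zeros_like(welch_grid)}, welch_grid)
        with pytest.raises(DataError):
            fit_psd_model(psd, "C3")

    def test_narrow_band_rejected(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        with pytest.raises(ParameterError):
            fit_psd_model(psd, "C3", fit_band_hz=(9.0, 11.0))

    def test_db_scale_option(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False, scale="db")
        assert fit.converged
        assert fit.params.mu == pytest.approx(10.0, abs=0.1)

    def test_noisy_recovery_median_error(self, single_peak_params):
        # 50 seeded replicates with 5% multiplicative noise
        errs = []
        for seed in range(50):
            psd = sample_model_psd(single_peak_params, FIT_GRID, 0.05, seed=seed)
            fit = fit_psd_model(psd, "C3", two_peaks=False, n_restarts=1)
            errs.append(
                [
                    abs(fit.params.k2 + 1.2) / 1.2,
                    abs(fit.params.mu - 10.0) / 10.0,
                    abs(fit.params.sigma - 1.0),
                ]
            )
        med = np.median(np.array(errs), axis=0)
        assert np.all(med <= 0.05)


class TestComputePredictor:
    def test_closed_form_index(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        index, method = compute_predictor(fit, psd)
        assert method == METHOD_MODEL
        expected = 8.0 / SQRT_2PI
        assert index == pytest.approx(expected, rel=5e-4)

    def test_power_law_only_falls_back_to_zero(self):
        p = ModelParams(1.0, 50.0, -1.2, 0.0, 10.0, 1.0)
        psd = sample_model_psd(p, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        index, method = compute_predictor(fit, psd)
        assert method == METHOD_PSD
        assert index == pytest.approx(0.0, abs=1e-6 * np.max(psd.power))

    def test_nonconverged_fit_uses_psd_fallback(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        good = fit_psd_model(psd, "C3", two_peaks=False)
        forced = SpectralModelFit(
            params=good.params,
            freqs_hz=good.freqs_hz,
            fitted=good.fitted,
            power_law=good.power_law,
            residual_rms=good.residual_rms,
            converged=False,
            fit_band_hz=good.fit_band_hz,
            channel=good.channel,
        )
        index, method = compute_predictor(forced, psd)
        assert method == METHOD_PSD
        assert index > 0

    def test_monotonic_in_peak_area(self):
        # larger a3 -> strictly larger primary index (closed-form evaluation)
        indices = []
        for a3 in (1.0, 2.0, 4.0, 8.0):
            p = ModelParams(1.0, 50.0, -1.2, a3, 10.0, 1.0)
            psd = sample_model_psd(p, FIT_GRID)
            fit = fit_psd_model(psd, "C3", two_peaks=False)
            idx, _ = compute_predictor(fit, psd)
            indices.append(idx)
        assert all(b > a for a, b in zip(indices, indices[1:]))

    def test_uniform_scaling_equivariance(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        idx, _ = compute_predictor(fit, psd)
        scaled = sample_model_psd(
            ModelParams(10.0, 500.0, -1.2, 80.0, 10.0, 1.0), FIT_GRID
        )
        fit10 = fit_psd_model(scaled, "C3", two_peaks=False)
        idx10, _ = compute_predictor(fit10, scaled)
        assert idx10 == pytest.approx(10.0 * idx, rel=1e-3)

    def test_grid_mismatch(self, single_peak_params):
        psd = sample_model_psd(single_peak_params, FIT_GRID)
        other = sample_model_psd(single_peak_params, FIT_GRID + 0.1)
        fit = fit_psd_model(psd, "C3", two_peaks=False)
        with pytest.raises(GridError):
            compute_predictor(fit, other)


def test_combine_predictors_mean():
    result = combine_predictors({"C3": (2.0, METHOD_MODEL), "C4": (4.0, METHOD_PSD)})
    assert result.combined == 3.0
    assert result.method_per_channel == {"C3": METHOD_MODEL, "C4": METHOD_PSD}
    with pytest.raises(ParameterError):
        combine_predictors({})
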