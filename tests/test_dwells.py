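"""Photobleaching correction, gamma fits and the length regression."""

import numpy as np
import pandas as pd
import pytest

from plugdyn.dwells import (
    PhotobleachPDF,
    deconvolve_dwells,
    fit_dwell_atp_model,
    fit_gamma,
    fit_length_dependence,
    missed_event_fraction,
    photobleach_pdf,
)


class TestPhotobleachPDF:
    def test_exponential_mean_recovered(self):
        rng = np.random.default_rng(0)
        pb = photobleach_pdf(rng.exponential(50.0, 500))
        assert abs(pb.mean_s - 50.0) / 50.0 < 0.10

    def test_censored_entries_raise_mean(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(50.0, 300)
        obs = t[t < 60]
        pb_naive = photobleach_pdf(obs)
        pb_cens = photobleach_pdf(obs, censoring_times=np.full((t >= 60).sum(),
                                                              60.0))
        assert pb_cens.mean_s > pb_naive.mean_s
        assert abs(pb_cens.mean_s - 50.0) / 50.0 < 0.15

    def test_truncation_robust_to_early_selection(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(30.0, 2000)
        kept = t[t > 6.0]                         # early-bleach traces culled
        naive = photobleach_pdf(kept).mean_s
        robust = photobleach_pdf(kept, truncation_s=10.0).mean_s
        assert abs(naive - 36.0) < 2.0            # inflated by truncation
        assert abs(robust - 30.0) < 2.5

    def test_too_few_events_nonparametric_flagged(self):
        with pytest.warns(UserWarning):
            pb = photobleach_pdf(np.linspace(1, 10, 5))
        assert pb.flagged and not pb.parametric

    def test_degenerate_times_flagged(self):
        with pytest.warns(UserWarning):
            pb = photobleach_pdf(np.full(50, 7.0))
        assert pb.flagged

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            photobleach_pdf([])

    def test_survival_is_exponential(self):
        pb = PhotobleachPDF(mean_s=10.0, times=np.array([10.0]))
        assert pb.survival(10.0) == pytest.approx(np.exp(-1.0))


class TestDeconvolution:
    def test_identity_limit_when_bleaching_negligible(self):
        rng = np.random.default_rng(3)
        dwells = rng.gamma(4.0, 2.0, 3000)
        pb = photobleach_pdf(rng.exponential(500.0, 200))
        res = deconvolve_dwells(dwells, pb)
        assert abs(res.mean_s - 8.0) / 8.0 < 0.05

    def test_censored_gamma_recovered_within_15pct(self):
        rng = np.random.default_rng(4)
        true = rng.gamma(4.0, 2.0, 4000)          # mean 8 s
        bleach = rng.exponential(10.0, 4000)
        observed = true[true < bleach]
        pb = photobleach_pdf(rng.exponential(10.0, 300))
        res = deconvolve_dwells(observed, pb)
        assert abs(res.mean_s - 8.0) / 8.0 < 0.15

    def test_fast_bleaching_flagged_unidentifiable(self):
        rng = np.random.default_rng(5)
        true = rng.gamma(4.0, 2.0, 3000)
        bleach = rng.exponential(1.0, 3000)
        observed = true[true < bleach]
        pb = photobleach_pdf(rng.exponential(1.0, 200))
        res = deconvolve_dwells(observed, pb)
        assert any("unidentifiable" in f for f in res.flags)

    def test_corrected_density_is_proper(self):
        rng = np.random.default_rng(6)
        res = deconvolve_dwells(rng.gamma(3.0, 1.5, 2000),
                                photobleach_pdf(rng.exponential(20.0, 100)))
        centres = 0.5 * (res.edges[:-1] + res.edges[1:])
        for dens in (res.corrected_density, res.nonparametric_density):
            assert np.all(dens >= 0)
            assert np.trapezoid(dens, centres) == pytest.approx(1.0, abs=0.05)


class TestGammaFit:
    def test_exponential_data_shape_near_one(self):
        rng = np.random.default_rng(7)
        shape, scale, _ = fit_gamma(rng.exponential(3.0, 2000))
        assert abs(shape - 1.0) < 0.1

    def test_gamma_4_2_recovered(self):
        rng = np.random.default_rng(8)
        shape, scale, p = fit_gamma(rng.gamma(4.0, 2.0, 1000))
        assert abs(shape - 4.0) < 0.5
        assert p > 0.01

    def test_constant_dwells_flagged(self):
        with pytest.warns(UserWarning):
            shape, _, _ = fit_gamma(np.full(100, 2.0))
        assert np.isinf(shape)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([1.0, -2.0])


class TestLengthDependence:
    LENGTHS = np.array([100, 233, 354, 683])

    def _noiseless(self):
        rows = []
        for L in self.LENGTHS:
            for _ in range(10):
                rows.append(dict(length_aa=L, duration_s=0.5 + L / 40.0))
        return pd.DataFrame(rows)

    def test_noiseless_exact_line(self):
        fit = fit_length_dependence(self._noiseless())
        assert fit.slope_s_per_aa == pytest.approx(0.025, rel=1e-9)
        assert fit.rate_aa_per_s == pytest.approx(40.0, rel=1e-9)
        assert fit.intercept_s == pytest.approx(0.5, rel=1e-9)

    def test_permuted_lengths_null_slope(self):
        rng = np.random.default_rng(9)
        df = self._noiseless()
        df["duration_s"] = 3.0 + 0.5 * rng.standard_normal(len(df))
        fit = fit_length_dependence(df)
        assert abs(fit.slope_s_per_aa) < 3 * fit.slope_se

    def test_single_length_rejected(self):
        df = pd.DataFrame({"length_aa": [100] * 5,
                           "duration_s": [1, 2, 3, 4, 5.0]})
        with pytest.raises(ValueError):
            fit_length_dependence(df)

    def test_ipcw_removes_censoring_bias(self):
        rng = np.random.default_rng(10)
        rows = []
        for L in self.LENGTHS:
            mean = 0.5 + L / 40.0
            true = rng.gamma(4.0, mean / 4.0, 600)
            bleach = rng.exponential(30.0, 600)
            for d in true[true < bleach]:
                rows.append(dict(length_aa=L, duration_s=d))
        df = pd.DataFrame(rows)
        pb = PhotobleachPDF(mean_s=30.0, times=np.array([30.0]))
        naive = fit_length_dependence(df)
        corrected = fit_length_dependence(df, pb)
        assert abs(corrected.rate_aa_per_s - 40.0) < abs(naive.rate_aa_per_s
                                                         - 40.0)
        assert abs(corrected.rate_aa_per_s - 40.0) / 40.0 < 0.10

    def test_missed_event_fraction_extrapolation(self):
        rng = np.random.default_rng(11)
        closed = rng.exponential(8.0, 3000)
        observed = closed[closed >= 0.4]
        p, mean = missed_event_fraction(observed, 0.4)
        assert p == pytest.approx(1 - np.exp(-0.4 / 8.0), rel=0.1)
        assert mean == pytest.approx(8.0, rel=0.1)


class TestAtpDwellModel:
    def test_noiseless_exact_amplitude(self):
        atp = np.array([0.025, 0.05, 0.2, 1.0])
        df = pd.DataFrame({"atp": atp, "dwell_s": 2.0 * (1 + 0.05 / atp)})
        fit = fit_dwell_atp_model(df, K_M=0.05)
        assert fit.amplitude_s == pytest.approx(2.0, rel=1e-9)

    def test_half_saturation_identity(self):
        fit = fit_dwell_atp_model(
            pd.DataFrame({"atp": [0.05, 1.0], "dwell_s": [4.0, 2.1]}),
            K_M=0.05)
        assert fit.curve([0.05])[0] == pytest.approx(2 * fit.amplitude_s)

    def test_noisy_recovery_within_15pct(self):
        rng = np.random.default_rng(12)
        atp = np.array([0.025, 0.1, 0.5, 2.0])
        y = 2.0 * (1 + 0.05 / atp) * (1 + 0.2 * rng.standard_normal(4))
        fit = fit_dwell_atp_model(pd.DataFrame({"atp": atp, "dwell_s": y}),
                                  K_M=0.05)
        assert abs(fit.amplitude_s - 2.0) / 2.0 < 0.15

    def test_nonpositive_atp_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_atp_model(pd.DataFrame({"atp": [0.0, 1.0],
                                              "dwell_s": [1.0, 1.0]}))
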