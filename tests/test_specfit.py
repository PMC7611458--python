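"""Linear-combination fitting, CRLBs, screening and quality metrics."""

import numpy as np
import pytest

from mrsquant.acquisition import AcquisitionParams
from mrsquant.basis import MetaboliteTemplate, SpinGroup, render_basis
from mrsquant.simulate import make_spectrum
from mrsquant.specfit import (
    FitConfig,
    GridError,
    SpectralFitModel,
    Spectrum,
    crlb_from_jacobian,
    fit_linear_combination,
    quality_metrics,
    screen_crlb,
)

LINEAR_CFG = FitConfig(fit_baseline=False, fit_shift=False, fit_broaden=False)


def flat_spectrum(basis, intensity=None):
    if intensity is None:
        intensity = np.zeros_like(basis.ppm)
    return Spectrum(ppm=basis.ppm, intensity=intensity, acq=basis.acq)


class TestAmplitudeRecovery:
    def test_noiseless_naa_naag_mixture_recovered(self, small_basis):
        truth = {"NAA": 8.94, "NAAG": 2.09}
        spec = make_spectrum(truth, small_basis, target_snr=None)
        fit = fit_linear_combination(spec, small_basis)
        for m, c in truth.items():
            assert abs(fit.amplitudes[m] - c) / c < 1e-6
        for m in ("Cr", "Ins", "Glu", "GPC"):
            assert fit.amplitudes[m] < 1e-6

    def test_zero_spectrum_gives_zero_amplitudes(self, small_basis):
        fit = fit_linear_combination(flat_spectrum(small_basis), small_basis)
        assert all(a == 0 for a in fit.amplitudes.values())

    def test_amplitude_linearity_under_scaling(self, small_basis):
        truth = {"NAA": 5.0, "Ins": 3.0}
        spec = make_spectrum(truth, small_basis, target_snr=None)
        doubled = Spectrum(spec.ppm, 2 * spec.intensity, spec.acq)
        f1 = fit_linear_combination(spec, small_basis)
        f2 = fit_linear_combination(doubled, small_basis)
        for m in truth:
            assert np.isclose(f2.amplitudes[m], 2 * f1.amplitudes[m], rtol=1e-5)

    def test_median_noisy_error_below_five_percent(self, small_basis):
        # Monte-Carlo oracle at the study's S/N
        truth = {"NAA": 8.94, "NAAG": 2.09, "Cr": 4.5, "Ins": 8.1, "Glu": 7.5, "GPC": 1.3}
        errs = []
        for seed in range(50):
            spec = make_spectrum(truth, small_basis, target_snr=26.0, seed=seed)
            fit = fit_linear_combination(spec, small_basis)
            errs.append(abs(fit.amplitudes["NAA"] - truth["NAA"]) / truth["NAA"])
        assert np.median(errs) < 0.05

    def test_nonoverlapping_grid_rejected(self, small_basis):
        other = AcquisitionParams(ppm_reference=30.0, field_strength=7.0)
        spec = Spectrum(other.ppm_axis, np.zeros(other.n_points), other)
        with pytest.raises(GridError):
            SpectralFitModel(spec, small_basis)

    def test_grid_mismatch_requires_resample_flag(self, small_basis):
        acq = AcquisitionParams(n_points=1024)
        spec = Spectrum(acq.ppm_axis, np.zeros(1024), acq)
        with pytest.raises(GridError, match="allow_resample"):
            SpectralFitModel(spec, small_basis)
        SpectralFitModel(spec, small_basis, FitConfig(allow_resample=True))


class TestSeparability:
    def test_joint_optimum_matches_brute_force_grid(self, small_basis):
        # brute-force oracle over (shift, broadening) x linear solve
        truth = {"NAA": 8.0, "Ins": 6.0}
        spec = make_spectrum(
            truth, small_basis, target_snr=None, target_fwhm_ppm=0.025
        )
        shifted = Spectrum(
            spec.ppm, np.interp(spec.ppm - 0.01, spec.ppm, spec.intensity), spec.acq
        )
        cfg = FitConfig(fit_baseline=False)
        model = SpectralFitModel(shifted, small_basis, cfg)
        fit = model.fit()
        y = shifted.intensity[model.window]
        best = np.inf
        for s in np.linspace(-0.02, 0.02, 21):
            for g in np.linspace(5.0, 10.0, 11):
                _, rss = model._linear_solve(model._design(s, g), y)
                best = min(best, rss)
        denom = float(np.sum(y**2))
        assert fit.rss <= best + 1e-3 * denom
        assert abs(fit.shift_ppm - 0.01) < 2e-3


class TestCRLB:
    def _single_line_basis(self):
        acq = AcquisitionParams(n_points=4096)
        tpl = MetaboliteTemplate("Cr", (SpinGroup(3.0, 1),))
        return render_basis([tpl], acq, lorentz_fwhm_hz=6.0)

    def test_single_lorentzian_matches_analytic_fisher_information(self):
        # closed form for one amplitude-only Lorentzian: CRLB = sigma*sqrt(h*pi*gamma)
        bs = self._single_line_basis()
        sigma = 0.02
        rng = np.random.default_rng(0)
        spec = Spectrum(
            bs.ppm, bs.rendered["Cr"] + rng.normal(0, sigma, bs.acq.n_points), bs.acq
        )
        cfg = FitConfig(fit_baseline=False, fit_shift=False, fit_broaden=False)
        model = SpectralFitModel(spec, bs, cfg, metabolites=["Cr"])
        fit = model.fit()
        J = model.jacobian(fit)
        crlb = crlb_from_jacobian(J, sigma)[0]
        gamma_ppm = 6.0 / bs.acq.hz_per_ppm
        analytic = sigma * np.sqrt(bs.acq.ppm_step * np.pi * gamma_ppm)
        assert abs(crlb - analytic) / analytic < 0.02

    def test_duplicate_basis_columns_blow_up_crlb(self, small_acq):
        tplA = MetaboliteTemplate("NAA", (SpinGroup(2.008, 3),))
        tplB = MetaboliteTemplate("NAAG", (SpinGroup(2.008, 3),))
        bs = render_basis([tplA, tplB], small_acq)
        rng = np.random.default_rng(1)
        spec = Spectrum(
            bs.ppm,
            5 * bs.rendered["NAA"] + rng.normal(0, 0.01, small_acq.n_points),
            small_acq,
        )
        fit = SpectralFitModel(spec, bs, LINEAR_CFG).fit()
        # collinear design: bounds diverge or are flagged unavailable
        assert (
            not fit.crlb_available
            or min(fit.crlb_pct.values()) > 1e3
        )

    def test_monte_carlo_sd_agrees_with_crlb(self, small_acq):
        tplA = MetaboliteTemplate("NAA", (SpinGroup(2.008, 3),))
        tplB = MetaboliteTemplate("Cr", (SpinGroup(3.027, 3),))
        bs = render_basis([tplA, tplB], small_acq)
        sigma = 0.05
        clean = 8.0 * bs.rendered["NAA"] + 4.5 * bs.rendered["Cr"]
        rng = np.random.default_rng(2)
        amps = []
        crlb = None
        for _ in range(500):
            spec = Spectrum(
                bs.ppm, clean + rng.normal(0, sigma, small_acq.n_points), small_acq
            )
            model = SpectralFitModel(spec, bs, LINEAR_CFG)
            fit = model.fit()
            amps.append(fit.amplitudes["NAA"])
            if crlb is None:
                J = model.jacobian(fit)
                crlb = crlb_from_jacobian(J, sigma)[0]
        ratio = np.std(amps, ddof=1) / crlb
        assert 0.8 < ratio < 1.2

    def test_crlb_scales_inversely_with_sqrt_averages(self, small_acq):
        tpl = MetaboliteTemplate("NAA", (SpinGroup(2.008, 3),))
        bs = render_basis([tpl], small_acq)
        clean = 8.0 * bs.rendered["NAA"]
        sigma = 0.08
        crlbs = []
        for n_avg in (1, 4, 16):
            s = sigma / np.sqrt(n_avg)
            rng = np.random.default_rng(3)
            spec = Spectrum(
                bs.ppm, clean + rng.normal(0, s, small_acq.n_points), small_acq
            )
            model = SpectralFitModel(spec, bs, LINEAR_CFG)
            fit = model.fit()
            crlbs.append(crlb_from_jacobian(model.jacobian(fit), s)[0])
        assert np.isclose(crlbs[0] / crlbs[1], 2.0, rtol=1e-6)
        assert np.isclose(crlbs[1] / crlbs[2], 2.0, rtol=1e-6)


class TestScreening:
    def test_threshold_rule(self):
        retained, excluded = screen_crlb({"NAA": 8.0, "Lac": 0.5}, {"NAA": 2.5, "Lac": 35.0})
        assert retained == {"NAA": 8.0}
        assert excluded == ["Lac"]

    def test_strict_inequality_at_threshold(self):
        amps = {"A" + str(i): 1.0 for i in range(5)}
        crlbs = {k: 19.9 for k in amps}
        retained, excluded = screen_crlb(amps, crlbs)
        assert len(retained) == 5 and excluded == []
        crlbs20 = {k: 20.0 for k in amps}
        retained, excluded = screen_crlb(amps, crlbs20)
        assert retained == {} and len(excluded) == 5

    def test_empty_input(self):
        assert screen_crlb({}, {}) == ({}, [])

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            screen_crlb({"NAA": 1.0}, {"Ins": 5.0})


class TestQualityMetrics:
    def test_noiseless_fwhm_matches_target(self, small_basis):
        spec = make_spectrum(
            {"NAA": 8.94}, small_basis, target_snr=None, target_fwhm_ppm=0.03
        )
        fit = fit_linear_combination(spec, small_basis)
        qm = quality_metrics(spec, fit)
        assert abs(qm.fwhm_ppm - 0.03) <= small_basis.acq.ppm_step

    def test_doubling_noise_halves_snr(self, small_basis):
        truth = {"NAA": 8.94, "Cr": 4.5}
        ratios = []
        for seed in range(20):
            s1 = make_spectrum(truth, small_basis, target_snr=30.0, seed=seed)
            s2 = make_spectrum(truth, small_basis, target_snr=15.0, seed=seed)
            q1 = quality_metrics(s1, fit_linear_combination(s1, small_basis))
            q2 = quality_metrics(s2, fit_linear_combination(s2, small_basis))
            ratios.append(q1.snr / q2.snr)
        assert abs(np.mean(ratios) - 2.0) / 2.0 < 0.1

    def test_pure_noise_flagged_low_signal(self, small_basis):
        rng = np.random.default_rng(4)
        spec = flat_spectrum(
            small_basis, rng.normal(0, 1.0, small_basis.acq.n_points)
        )
        fit = fit_linear_combination(spec, small_basis)
        qm = quality_metrics(spec, fit)
        assert qm.low_signal

    def test_noise_region_outside_grid_rejected(self, small_basis):
        spec = make_spectrum({"NAA": 5.0}, small_basis, target_snr=None)
        with pytest.raises(GridError, match="noise region"):
            SpectralFitModel(spec, small_basis, FitConfig(noise_region_ppm=(14.0, 15.0)))
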