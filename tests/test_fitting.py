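"""Model fitting: recovery, constraints, localization-error inference."""

import numpy as np
import pytest

from sptfit import (
    AcquisitionSettings,
    FitSpec,
    ModelParams2,
    benchmark_config,
    build_histograms,
    compare_pdf_cdf,
    compute_displacements,
    fit_model,
    infer_localization_error,
    model_distribution,
    simulate_dataset,
)
from sptfit.empirical import JumpHistogram


def hist_from_model(params, settings, edges, coeffs, n_jumps=10_000):
    """Noise-free histogram generated from the model itself."""
    curve = model_distribution(params, settings, edges, coeffs)
    pdf = curve.density_per_lag
    return JumpHistogram(
        bin_edges=np.asarray(edges, dtype=float),
        counts_per_lag=(pdf * n_jumps).astype(np.int64),
        pdf_per_lag=pdf,
        cdf_per_lag=np.cumsum(pdf, axis=1),
        n_jumps_per_lag=np.full(settings.n_lags, n_jumps),
        dt=settings.dt,
    )


class TestFitModel:
    def test_noise_free_fixed_point(self, coeffs):
        truth = ModelParams2(d_bound=0.02, d_free=3.0, f_bound=0.6, sigma=0.03)
        settings = AcquisitionSettings(dt=0.01, dz=0.7, gaps=1, n_lags=5)
        edges = np.arange(0, 3.0 + 0.01, 0.01)
        hist = hist_from_model(truth, settings, edges, coeffs)
        for mode in ("pdf", "cdf"):
            spec = FitSpec(mode=mode, fixed_sigma=0.03, n_restarts=3, seed=0)
            fit = fit_model(hist, settings, spec, coeffs)
            assert fit.params.d_free == pytest.approx(3.0, rel=1e-4)
            assert fit.params.f_bound == pytest.approx(0.6, abs=1e-4)
            assert fit.params.d_bound == pytest.approx(0.02, rel=1e-3)

    def test_simplex_constraint_exact(self, sim_reference, coeffs):
        fit = fit_model(sim_reference["hist"], sim_reference["settings"],
                        FitSpec(fixed_sigma=0.025, seed=1), coeffs)
        p = fit.params
        assert 0.0 <= p.f_bound <= 1.0
        assert p.f_bound + p.f_free == 1.0

    def test_restart_dominance(self, sim_reference, coeffs):
        fit = fit_model(sim_reference["hist"], sim_reference["settings"],
                        FitSpec(fixed_sigma=0.025, n_restarts=4, seed=3), coeffs)
        converged = [r.objective for r in fit.restarts if r.converged]
        assert fit.objective <= min(converged) + 1e-12

    def test_reference_condition_recovery(self, sim_reference, coeffs):
        """Mostly-bound, slow-diffusion benchmark condition: the bound
        fraction is recovered within 2 points and the diffusion constant
        within the confinement-dominated -10%..0% window."""
        fit = fit_model(sim_reference["hist"], sim_reference["settings"],
                        FitSpec(mode="cdf", fixed_sigma=0.025, seed=1), coeffs)
        d_true = sim_reference["d_free"]
        assert fit.params.f_bound == pytest.approx(sim_reference["f_bound"],
                                                   abs=0.02)
        rel = (fit.params.d_free - d_true) / d_true
        assert -0.10 <= rel <= 0.0

    def test_disabling_correction_inflates_bound_fraction(self, coeffs):
        # fast diffusion at slow frame rate: without the defocalization
        # factor the vanishing free molecules are absorbed into the bound pool
        cfg = benchmark_config(14.0, 0.50, 0.02, target_trajectories=20_000,
                               seed=42)
        ts = simulate_dataset(cfg).trajectories
        hist = build_histograms(compute_displacements(ts, 3, None),
                                0.01, 6.0, dt=0.02)
        settings = AcquisitionSettings(dt=0.02, dz=0.7, gaps=1, n_lags=3)
        on = fit_model(hist, settings,
                       FitSpec(fixed_sigma=0.025, seed=1), coeffs)
        off = fit_model(hist, settings,
                        FitSpec(fixed_sigma=0.025, seed=1, apply_zcorr=False),
                        coeffs)
        assert off.params.f_bound > 0.50 + 0.15
        assert off.params.f_bound > on.params.f_bound + 0.15

    def test_empty_histogram_rejected(self, coeffs):
        settings = AcquisitionSettings(dt=0.01, dz=0.7, gaps=1, n_lags=2)
        hist = JumpHistogram(
            bin_edges=np.array([0.0, 0.1]),
            counts_per_lag=np.zeros((2, 1), dtype=np.int64),
            pdf_per_lag=np.full((2, 1), np.nan),
            cdf_per_lag=np.full((2, 1), np.nan),
            n_jumps_per_lag=np.zeros(2, dtype=np.int64),
            dt=0.01,
        )
        with pytest.raises(ValueError, match="no lag with jumps"):
            fit_model(hist, settings, FitSpec(), coeffs)


class TestLocalizationErrorInference:
    def test_sigma_recovered_with_large_bound_fraction(self, sim_reference,
                                                       coeffs):
        fit = infer_localization_error(
            sim_reference["hist"], sim_reference["settings"],
            FitSpec(mode="cdf", seed=1), coeffs)
        # simulation truth is 25 nm; inference is expected at nm precision
        assert fit.params.sigma == pytest.approx(0.025, abs=0.005)
        assert not fit.sigma_unreliable

    def test_fixed_and_fitted_sigma_agree_on_f_bound(self, sim_reference,
                                                     coeffs):
        fixed = fit_model(sim_reference["hist"], sim_reference["settings"],
                          FitSpec(fixed_sigma=0.025, seed=1), coeffs)
        fitted = infer_localization_error(
            sim_reference["hist"], sim_reference["settings"],
            FitSpec(seed=1), coeffs)
        assert fitted.params.f_bound == pytest.approx(fixed.params.f_bound,
                                                      abs=0.01)

    def test_no_bound_fraction_flags_sigma_unreliable(self, coeffs):
        cfg = benchmark_config(8.0, 0.0, 0.004, target_trajectories=10_000,
                               seed=11)
        ts = simulate_dataset(cfg).trajectories
        hist = build_histograms(compute_displacements(ts, 8, None),
                                0.01, 6.0, dt=0.004)
        settings = AcquisitionSettings(dt=0.004, dz=0.7, gaps=1, n_lags=8)
        fit = infer_localization_error(hist, settings, FitSpec(seed=1), coeffs)
        assert fit.sigma_unreliable


class TestPdfCdfComparison:
    def test_noise_free_input_recovered_by_both_modes(self, coeffs):
        truth = ModelParams2(d_bound=0.01, d_free=5.0, f_bound=0.4, sigma=0.025)
        settings = AcquisitionSettings(dt=0.01, dz=0.7, gaps=1, n_lags=4)
        edges = np.arange(0, 4.0 + 0.01, 0.01)
        hist = hist_from_model(truth, settings, edges, coeffs)
        pair = compare_pdf_cdf(hist, settings,
                               FitSpec(fixed_sigma=0.025, seed=2), coeffs)
        for mode in ("pdf", "cdf"):
            assert pair[mode].params.d_free == pytest.approx(5.0, rel=1e-3)
            assert pair[mode].params.f_bound == pytest.approx(0.4, abs=1e-3)

    def test_modes_agree_on_large_dataset(self, sim_reference, coeffs):
        pair = compare_pdf_cdf(sim_reference["hist"],
                               sim_reference["settings"],
                               FitSpec(fixed_sigma=0.025, seed=1), coeffs)
        diff = abs(pair["pdf"].params.f_bound - pair["cdf"].params.f_bound)
        assert diff < 0.01

    def test_small_datasets_give_stable_estimates_in_both_modes(self, coeffs):
        """~3,000 short trajectories: both modes stay within a few points of
        the truth across random replicates."""
        f_pdf, f_cdf = [], []
        for s in range(6):
            cfg = benchmark_config(2.0, 0.70, 0.007,
                                   target_trajectories=3_000, seed=100 + s)
            ts = simulate_dataset(cfg).trajectories
            hist = build_histograms(compute_displacements(ts, 7, None),
                                    0.01, 6.0, dt=0.007)
            settings = AcquisitionSettings(dt=0.007, dz=0.7, gaps=1, n_lags=7)
            pair = compare_pdf_cdf(hist, settings,
                                   FitSpec(fixed_sigma=0.025, seed=1), coeffs)
            f_pdf.append(pair["pdf"].params.f_bound)
            f_cdf.append(pair["cdf"].params.f_bound)
        for vals in (f_pdf, f_cdf):
            assert np.all(np.abs(np.array(vals) - 0.70) < 0.08)
            assert np.std(vals) < 0.04


class TestThreeState:
    def test_three_state_labels_ordered(self, coeffs):
        from sptfit import ModelParams3
        truth = ModelParams3(d_bound=0.005, d_slow=0.8, d_fast=8.0,
                             f_bound=0.3, f_slow=0.3, sigma=0.025)
        settings = AcquisitionSettings(dt=0.01, dz=0.7, gaps=1, n_lags=5)
        edges = np.arange(0, 4.0 + 0.01, 0.01)
        hist = hist_from_model(truth, settings, edges, coeffs)
        spec = FitSpec(n_states=3, mode="cdf", fixed_sigma=0.025,
                       n_restarts=4, seed=5)
        fit = fit_model(hist, settings, spec, coeffs)
        p = fit.params
        assert p.d_slow <= p.d_fast
        assert p.f_bound + p.f_slow + p.f_fast == pytest.approx(1.0, abs=1e-12)
        assert p.d_fast == pytest.approx(8.0, rel=0.05)
        assert p.f_bound == pytest.approx(0.3, abs=0.03)
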