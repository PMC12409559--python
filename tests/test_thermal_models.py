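import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btherm import TruthConfig, fit_exponential, fit_linear, fit_profile_series, global_b_fits
from btherm.thermal_models import exp_fit_batch

TEMPS = np.arange(100.0, 301.0, 25.0)


class TestFitLinear:
    def test_exact_line_recovered(self):
        y = 2.0 + 0.001 * TEMPS
        fit = fit_linear(TEMPS, y)
        assert fit.k == pytest.approx(0.001, abs=1e-12)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert fit.p_two_tailed < 1e-10

    def test_constant_response_degenerate(self):
        fit = fit_linear(TEMPS, np.full_like(TEMPS, 3.0))
        assert fit.k == 0.0
        assert fit.pearson_r == 0.0
        assert not fit.converged

    def test_identical_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([100.0, 100.0, 100.0], [1.0, 2.0, 3.0])

    def test_ols_beats_random_candidates(self):
        """OLS loss is never beaten by random (slope, intercept) proposals."""
        rng = np.random.default_rng(7)
        slopes = rng.normal(0, 0.01, 10_000)
        intercepts = rng.normal(0, 5, 10_000)
        for _ in range(50):
            y = rng.normal(0, 1, len(TEMPS)) + 0.002 * TEMPS
            fit = fit_linear(TEMPS, y)
            best = fit.amplitude + fit.k * TEMPS
            loss = ((y - best) ** 2).sum()
            cand = intercepts[:, None] + slopes[:, None] * TEMPS[None, :]
            cand_loss = ((y[None, :] - cand) ** 2).sum(axis=1)
            assert loss <= cand_loss.min() + 1e-12

    def test_matches_closed_form_solution(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=len(TEMPS))
            fit = fit_linear(TEMPS, y)
            slope, intercept = np.polyfit(TEMPS, y, 1)
            assert fit.k == pytest.approx(slope, abs=1e-12)
            assert fit.amplitude == pytest.approx(intercept, abs=1e-10)


class TestFitExponential:
    def test_exact_exponential_recovered(self):
        y = 10.0 * np.exp(0.005 * TEMPS)
        fit = fit_exponential(TEMPS, y)
        assert fit.amplitude == pytest.approx(10.0, abs=1e-8)
        assert fit.k == pytest.approx(0.005, abs=1e-10)
        assert fit.converged
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_fit_equals_log_seed(self):
        """With zero residual the nonlinear refinement cannot move away
        from the log-linear initializer."""
        y = 4.0 * np.exp(0.004 * TEMPS)
        ols = np.polyfit(TEMPS, np.log(y), 1)
        fit = fit_exponential(TEMPS, y)
        assert fit.k == pytest.approx(ols[0], abs=1e-8)
        assert fit.amplitude == pytest.approx(np.exp(ols[1]), abs=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        y = 8.0 * np.exp(0.005 * TEMPS) * (1 + rng.normal(0, 0.03, len(TEMPS)))
        f1 = fit_exponential(TEMPS, y)
        f2 = fit_exponential(TEMPS, 7.3 * y)
        assert f2.k == pytest.approx(f1.k, abs=1e-8)
        assert f2.amplitude == pytest.approx(7.3 * f1.amplitude, rel=1e-8)

    def test_temperature_shift_equivariance(self):
        rng = np.random.default_rng(10)
        y = 8.0 * np.exp(0.005 * TEMPS) * (1 + rng.normal(0, 0.03, len(TEMPS)))
        f1 = fit_exponential(TEMPS, y)
        f2 = fit_exponential(TEMPS + 50.0, y)
        assert f2.k == pytest.approx(f1.k, abs=1e-8)
        assert f2.amplitude == pytest.approx(f1.amplitude * np.exp(-f1.k * 50.0), rel=1e-6)

    def test_nonpositive_response_without_seed_flagged(self):
        fit = fit_exponential(TEMPS, np.full(len(TEMPS), -1.0))
        assert not fit.converged
        assert np.isnan(fit.amplitude)

    def test_too_few_distinct_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([100.0, 100.0, 200.0, 200.0], [1, 1, 2, 2])

    def test_matches_scipy_curve_fit(self):
        """Independent optimizer cross-check on noisy series."""
        from scipy.optimize import curve_fit
        rng = np.random.default_rng(11)
        t3 = np.repeat(TEMPS, 3)
        for _ in range(10):
            y = 6.0 * np.exp(0.0045 * t3) * (1 + rng.normal(0, 0.05, len(t3)))
            fit = fit_exponential(t3, y)
            popt, _ = curve_fit(lambda t, a, k: a * np.exp(k * t), t3, y,
                                p0=(fit.amplitude * 1.2, fit.k * 0.8), maxfev=10000)
            assert fit.amplitude == pytest.approx(popt[0], rel=1e-5)
            assert fit.k == pytest.approx(popt[1], abs=1e-7)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(1.0, 50.0), st.floats(0.001, 0.01))
    def test_parameter_recovery_noiseless(self, b0, k):
        fit = fit_exponential(TEMPS, b0 * np.exp(k * TEMPS))
        assert fit.amplitude == pytest.approx(b0, rel=1e-7)
        assert fit.k == pytest.approx(k, abs=1e-9)


class TestExpFitBatch:
    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(12)
        Y = np.stack([b0 * np.exp(k * TEMPS) * (1 + rng.normal(0, 0.05, len(TEMPS)))
                      for b0, k in [(5, 0.004), (20, 0.006), (1.5, 0.002)]])
        A, K, _, conv, _ = exp_fit_batch(TEMPS, Y)
        for i in range(3):
            f = fit_exponential(TEMPS, Y[i])
            assert A[i] == pytest.approx(f.amplitude, rel=1e-9)
            assert K[i] == pytest.approx(f.k, abs=1e-12)

    def test_missing_values_ignored(self):
        Y = np.tile(3.0 * np.exp(0.005 * TEMPS), (2, 1))
        Y[0, [1, 4]] = np.nan
        A, K, _, conv, nv = exp_fit_batch(TEMPS, Y)
        assert nv[0] == len(TEMPS) - 2
        assert K[0] == pytest.approx(0.005, abs=1e-8)

    def test_unseedable_row_flagged(self):
        Y = np.vstack([np.full(len(TEMPS), -2.0), 3.0 * np.exp(0.005 * TEMPS)])
        A, K, _, conv, _ = exp_fit_batch(TEMPS, Y)
        assert np.isnan(A[0]) and not conv[0]
        assert conv[1]


class TestFitProfileSeries:
    def test_noiseless_recovers_per_residue_truth(self, noiseless_ensemble):
        series, truth = noiseless_ensemble
        tab = fit_profile_series(series, "calpha", "b_raw")
        merged = tab.merge(truth.residues, on="resseq", suffixes=("_fit", "_true"))
        assert len(merged) == len(truth.residues)
        # limited only by the PDB B-field quantization (0.01 A^2)
        assert np.abs(merged["k_fit"] - merged["k_true"]).max() < 1e-4
        assert np.allclose(merged["amplitude"], merged["b0"], rtol=0.02)

    def test_uniform_k_normalized_fits_are_flat(self, base40):
        """When every residue shares one thermal constant, normalization
        cancels the exponential factor and the fitted norm-k collapse to
        zero."""
        from btherm import generate_ensemble
        series, _ = generate_ensemble(
            base40, TruthConfig.noiseless(k_mode="fixed"), seed=31)
        tab = fit_profile_series(series, "calpha", "b_norm")
        assert np.abs(tab["k"]).max() < 1e-4

    def test_low_coverage_residues_omitted(self, noiseless_ensemble):
        series, truth = noiseless_ensemble
        import pandas as pd
        long = []
        for m in series.models:
            from btherm import aggregate_b
            prof = aggregate_b(m, "calpha").data.rename(columns={"b_raw": "value"})
            prof["structure_id"] = m.structure_id
            prof["temperature_K"] = m.temperature_K
            long.append(prof)
        long = pd.concat(long, ignore_index=True)
        # residue 7 appears in only 2 structures
        keep = ~((long["resseq"] == 7) &
                 (~long["structure_id"].isin(["S100R1", "S125R1"])))
        tab = fit_profile_series(series, "calpha", "b_raw",
                                 long_table=long[keep])
        assert 7 not in tab["resseq"].tolist()

    def test_empty_series_rejected(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        from btherm import TemperatureSeries
        with pytest.raises(ValueError):
            bad = TemperatureSeries(models=[series.models[0]],
                                    reference_id=series.models[0].structure_id)
            fit_profile_series(bad, "calpha", "b_raw")


class TestGlobalBFits:
    def test_noiseless_channels_recover_shared_truth(self, base40):
        from btherm import generate_ensemble
        cfg = TruthConfig.noiseless(k_mode="fixed", k_fixed=0.004,
                                    b0_sigma_log=0.0, b0_median=5.6,
                                    sc_b0_factor=1.0, nonprotein_k=0.004)
        series, _ = generate_ensemble(base40, cfg, seed=41)
        fits = global_b_fits(series)
        for ch in ("side_chain", "calpha"):
            assert fits[ch].k == pytest.approx(0.004, abs=2e-5)
            assert fits[ch].amplitude == pytest.approx(5.6, rel=0.01)
        assert fits["mean_k"] == pytest.approx(0.004, abs=5e-4)

    def test_missing_wilson_channel_skipped(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        import dataclasses
        models = [dataclasses.replace(m, wilson_b=None) for m in series.models]
        from btherm import TemperatureSeries
        s2 = TemperatureSeries(models=models, reference_id=series.reference_id)
        with pytest.warns(UserWarning):
            fits = global_b_fits(s2)
        assert fits["wilson"] is None
        assert np.isfinite(fits["mean_k"])
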