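"""Nonlinear estimation: identifiability, censoring, diagnostics."""

import math

import numpy as np
import pytest

from zfpk.core_pk import PKParameters, Route
from zfpk.fitting import (
    FitOptions,
    IdentifiabilityWarning,
    censor_outliers,
    censor_window,
    fit_pk,
    fit_with_censoring,
    half_life,
    initial_estimates,
    residual_diagnostics,
)
from zfpk.synthetic_data import NoiseModel, QuenchSpec, simulate_dataset


class TestHalfLife:
    def test_ln2_identity(self):
        assert half_life(math.log(2.0)) == pytest.approx(1.0, rel=1e-15)

    @pytest.mark.parametrize("ke, expected", [(0.052, 13.33), (0.011, 63.01)])
    def test_reported_rate_constants(self, ke, expected):
        assert half_life(ke) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_ke_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestInitialEstimates:
    def test_close_to_truth_on_noiseless_data(self, noiseless_dataset, truth):
        for name in ("CY3A", "TAMRA"):
            start = initial_estimates(noiseless_dataset, name)
            assert start.ke == pytest.approx(truth[name].ke, rel=0.10)
            assert start.fluor == pytest.approx(truth[name].fluor, rel=0.10)
            assert start.q == pytest.approx(truth[name].q, rel=0.35)

    def test_log_linear_slope_recovers_pure_monoexponential(self, design, truth):
        p = PKParameters(fluor=5000.0, ke=0.05, q=1e-9)
        ds = simulate_dataset({"CY3A": p}, design["compounds"], design["regimens"],
                              3, NoiseModel(0.0, 0.0), None, seed=0)
        start = initial_estimates(ds, "CY3A")
        assert start.ke == pytest.approx(0.05, rel=0.05)

    def test_dead_immersion_signal_clips_q_and_warns(self, design, truth):
        p = PKParameters(fluor=5000.0, ke=0.05, q=1e-30)
        ds = simulate_dataset({"CY3A": p}, design["compounds"], design["regimens"],
                              3, NoiseModel(0.0, 0.0), None, seed=0)
        with pytest.warns(IdentifiabilityWarning):
            start = initial_estimates(ds, "CY3A")
        assert start.q > 0


class TestFitPk:
    def test_noiseless_recovery_to_1e4_relative(self, noiseless_dataset, truth):
        for name in truth:
            fit = fit_pk(noiseless_dataset, name)
            for attr in ("fluor", "ke", "q"):
                got = getattr(fit.params, attr)
                want = getattr(truth[name], attr)
                assert got == pytest.approx(want, rel=1e-4), (name, attr)
            assert fit.converged and fit.residual_standard_error < 1e-6 * truth[name].fluor

    def test_recovery_from_heavily_perturbed_starts(self, noiseless_dataset, truth):
        t = truth["CY3A"]
        for factor in (0.5, 1.5):
            start = PKParameters(fluor=t.fluor * factor, ke=t.ke * factor, q=t.q * factor)
            fit = fit_pk(noiseless_dataset, "CY3A", start=start)
            assert fit.params.ke == pytest.approx(t.ke, rel=1e-4)
            assert fit.params.q == pytest.approx(t.q, rel=1e-4)

    def test_half_life_propagates_from_fitted_ke(self, design, truth):
        p = PKParameters(fluor=4000.0, ke=0.052, q=1.45e-9)
        ds = simulate_dataset({"TAMRA": p}, design["compounds"], design["regimens"],
                              3, NoiseModel(0.0, 0.0), None, seed=1)
        fit = fit_pk(ds, "TAMRA")
        assert fit.half_life_h == pytest.approx(13.33, abs=0.01)

    def test_scale_equivariance_in_rfu_units(self, noisy_dataset, truth):
        """Rescaling all RFU by c rescales fluor by c and leaves ke, q fixed."""
        base = fit_pk(noisy_dataset, "CY3A")
        scaled = noisy_dataset.copy()
        scaled.observations["rfu"] *= 37.0
        fit = fit_pk(scaled, "CY3A")
        assert fit.params.fluor == pytest.approx(37.0 * base.params.fluor, rel=1e-6)
        assert fit.params.ke == pytest.approx(base.params.ke, rel=1e-8)
        assert fit.params.q == pytest.approx(base.params.q, rel=1e-8)

    def test_single_route_data_warns_about_identifiability(self, design, truth):
        inj = [r for r in design["regimens"] if r.route is Route.PC]
        ds = simulate_dataset({"CY3A": truth["CY3A"]}, design["compounds"], inj,
                              5, NoiseModel(0.05), None, seed=2)
        start = truth["CY3A"]
        with pytest.warns(IdentifiabilityWarning):
            fit_pk(ds, "CY3A", start=start)

    def test_standard_errors_scale_with_noise(self, design, truth):
        fits = []
        for cv in (0.05, 0.20):
            ds = simulate_dataset({"CY3A": truth["CY3A"]}, design["compounds"],
                                  design["regimens"], 10, NoiseModel(cv), None, seed=3)
            fits.append(fit_pk(ds, "CY3A"))
        assert fits[1].se["ke"] > fits[0].se["ke"]
        assert fits[1].se["q"] > fits[0].se["q"]


class TestCensoring:
    def test_noiseless_data_censors_nothing(self, noiseless_dataset):
        fit = fit_pk(noiseless_dataset, "CY3A")
        out = censor_outliers(noiseless_dataset, fit)
        assert out.observations["censored"].sum() == 0

    def test_infinite_threshold_is_a_no_op(self, noisy_dataset):
        fit = fit_pk(noisy_dataset, "CY3A")
        out = censor_outliers(noisy_dataset, fit,
                              FitOptions(censor_threshold=float("inf")))
        assert out.observations.equals(noisy_dataset.observations)

    def test_quench_artifacts_are_flagged_and_fit_recovers(self, design, truth):
        quench = QuenchSpec(affected_routes=frozenset({Route.PC}))
        three = [r for r in design["regimens"]
                 if r.route.value in ("immersion", "PC", "IP")]
        ds = simulate_dataset({"CY3A": truth["CY3A"]}, design["compounds"], three,
                              10, NoiseModel(0.10), quench, seed=17)
        fit, flagged = fit_with_censoring(ds, "CY3A")
        obs = flagged.observations
        artifact = (obs["route"] == "PC") & (obs["time_h"] < 1.0)
        assert (obs.loc[artifact, "censored"]).mean() >= 0.9
        assert fit.params.ke == pytest.approx(truth["CY3A"].ke, rel=0.10)

    def test_censored_set_grows_monotonically_and_terminates(self, design, truth):
        quench = QuenchSpec(affected_routes=frozenset({Route.PC}))
        ds = simulate_dataset({"CY3A": truth["CY3A"]}, design["compounds"],
                              design["regimens"], 10, NoiseModel(0.10), quench, seed=23)
        options = FitOptions(max_censor_rounds=3)
        fit = fit_pk(ds, "CY3A", options)
        counts = [0]
        current = ds
        for _ in range(options.max_censor_rounds):
            current = censor_outliers(current, fit, options)
            counts.append(int(current.observations["censored"].sum()))
            if counts[-1] == counts[-2]:
                break
            fit = fit_pk(current, "CY3A", options)
        assert counts == sorted(counts)
        assert len(counts) - 1 <= options.max_censor_rounds

    def test_window_mode_drops_early_injection_points_only(self, noisy_dataset):
        out = censor_window(noisy_dataset, "CY3A", cutoff_h=1.0)
        obs = out.observations
        target = ((obs["compound"] == "CY3A") & (obs["route"] != "immersion")
                  & (obs["time_h"] < 1.0))
        assert obs.loc[target, "censored"].all()
        assert not obs.loc[~target, "censored"].any()

    def test_excess_censoring_refused(self, design, truth):
        ds = simulate_dataset({"CY3A": truth["CY3A"]}, design["compounds"],
                              design["regimens"], 4, NoiseModel(0.0, 0.0), None, seed=0)
        fit = fit_pk(ds, "CY3A")
        broken = ds.copy()
        # corrupt most observations so the model cannot describe them
        n_bad = int(0.6 * len(broken.observations))
        broken.observations.loc[broken.observations.index[:n_bad], "rfu"] *= 25.0
        with pytest.raises(RuntimeError, match="50%"):
            censor_outliers(broken, fit, FitOptions(censor_threshold=2.5))


class TestDiagnostics:
    def test_noiseless_residuals_are_zero(self, noiseless_dataset):
        fit = fit_pk(noiseless_dataset, "FAMA")
        diag = residual_diagnostics(noiseless_dataset, fit)
        assert len(diag) == fit.n_used
        assert np.allclose(diag["residual"], 0.0, atol=1e-6)

    def test_well_specified_fit_is_unbiased(self, design, truth):
        """Mean standardized residual stays within ±0.2 across seeds."""
        biases = []
        for seed in range(20):
            ds = simulate_dataset({"TAMRA": truth["TAMRA"]}, design["compounds"],
                                  design["regimens"], 10, NoiseModel(0.10), None,
                                  seed=seed)
            fit = fit_pk(ds, "TAMRA")
            diag = residual_diagnostics(ds, fit)
            biases.append(diag["standardized_residual"].mean())
        assert np.all(np.abs(biases) < 0.2)
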