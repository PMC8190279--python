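"""Closed-form model, ODE oracle equivalence, steady state and AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfpk.core_pk import (
    CompoundRecord,
    ExposureRegimen,
    PKParameters,
    Route,
    amount_at_time,
    amount_trajectory_ode,
    auc,
    dose_amount,
    fluorescence,
    medium_concentration,
    read_config,
    regimen_params_from_config,
    regimen_params_to_config,
    steady_state_amount,
    write_config,
)

CY3A_MW = 530.14
CY3A = PKParameters(fluor=1.0, ke=0.049, q=8.37e-9)
IMM = ExposureRegimen(route=Route.IMMERSION, medium_conc_um=10.0)
INJ = ExposureRegimen(route=Route.PC, dose_mg_per_kg=2.0)
COMBO = ExposureRegimen(route=Route.COMBINATION, medium_conc_um=10.0, dose_mg_per_kg=2.0)


params_st = st.builds(
    PKParameters,
    fluor=st.floats(1e2, 1e4),
    ke=st.floats(5e-3, 0.5),
    q=st.floats(1e-10, 2e-8),
)


class TestUnitBridges:
    @pytest.mark.parametrize(
        "conc_um, mw, expected",
        [(0.0, 400.0, 0.0), (10.0, 530.14, 5.3014e6), (10.0, 1054.3, 1.05430e7)],
    )
    def test_micromolar_to_ng_per_l(self, conc_um, mw, expected):
        assert medium_concentration(conc_um, mw) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            medium_concentration(10.0, 0.0)

    @pytest.mark.parametrize(
        "dose, bw, expected", [(2.0, 0.25, 0.5), (0.0, 0.25, 0.0), (4.0, 0.25, 1.0)]
    )
    def test_dose_in_ng(self, dose, bw, expected):
        assert dose_amount(dose, bw) == expected

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_amount(-1.0, 0.25)


class TestAmountAtTime:
    def test_injection_at_time_zero_is_the_dose(self):
        assert amount_at_time(CY3A, INJ, 0.0) == pytest.approx(0.5, abs=0.0)

    def test_immersion_long_time_approaches_steady_state(self):
        ss = steady_state_amount(CY3A, IMM, mw=CY3A_MW)
        assert amount_at_time(CY3A, IMM, 1e5, mw=CY3A_MW) == pytest.approx(ss, rel=1e-9)

    def test_hand_evaluated_immersion_amount_at_48h(self):
        # 0.905 ng plateau times (1 - e^{-0.049*48})
        a = amount_at_time(CY3A, IMM, 48.0, mw=CY3A_MW)
        assert a == pytest.approx(0.9055657 * (1 - math.exp(-2.352)), rel=1e-6)
        assert a == pytest.approx(0.819, abs=5e-4)

    def test_missing_mw_for_immersion_raises(self):
        with pytest.raises(ValueError, match="MW"):
            amount_at_time(CY3A, IMM, 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=params_st, t=st.floats(0.0, 48.0))
    def test_combination_superposes_single_routes(self, params, t):
        both = amount_at_time(params, COMBO, t, mw=CY3A_MW)
        inj = amount_at_time(params, INJ, t)
        imm = amount_at_time(params, IMM, t, mw=CY3A_MW)
        assert both == pytest.approx(inj + imm, rel=1e-12, abs=1e-15)

    def test_injection_strictly_decreasing_immersion_increasing_and_bounded(self):
        t = np.linspace(0.0, 48.0, 200)
        inj = amount_at_time(CY3A, INJ, t)
        imm = amount_at_time(CY3A, IMM, t, mw=CY3A_MW)
        assert np.all(np.diff(inj) < 0)
        assert np.all(np.diff(imm) > 0)
        assert np.all(imm <= steady_state_amount(CY3A, IMM, mw=CY3A_MW))


class TestOdeOracle:
    def test_pure_decay_matches_exponential(self):
        t = np.array([0.0, 1.0, 6.0, 24.0, 48.0])
        traj = amount_trajectory_ode(CY3A, INJ, t)
        assert traj.amounts == pytest.approx(0.5 * np.exp(-0.049 * t), rel=1e-8)

    def test_uptake_monotone_and_bounded_by_plateau(self):
        t = np.linspace(0.25, 200.0, 50)
        traj = amount_trajectory_ode(CY3A, IMM, t, mw=CY3A_MW)
        assert np.all(np.diff(traj.amounts) > -1e-12)
        assert np.all(traj.amounts <= steady_state_amount(CY3A, IMM, mw=CY3A_MW) * (1 + 1e-9))

    def test_closed_form_agrees_with_ode_on_random_draws(self, rng):
        times = np.array([0.25, 1.0, 3.0, 6.0, 24.0, 48.0])
        for _ in range(20):
            params = PKParameters(
                fluor=1.0,
                ke=float(rng.uniform(5e-3, 0.5)),
                q=float(rng.uniform(1e-10, 2e-8)),
            )
            regimen = COMBO if rng.random() < 0.5 else (INJ if rng.random() < 0.5 else IMM)
            closed = amount_at_time(params, regimen, times, mw=CY3A_MW)
            traj = amount_trajectory_ode(params, regimen, times, mw=CY3A_MW)
            assert np.max(np.abs(traj.amounts - closed) / np.abs(closed)) < 1e-6


class TestFluorescenceScale:
    def test_linearity_and_degenerate_zero(self):
        assert fluorescence(CY3A, 0.0) == 0.0
        p = PKParameters(fluor=2000.0, ke=0.049, q=0.0)
        assert fluorescence(p, 0.5) == 1000.0

    def test_fluorescence_scale_auc_is_fluor_times_amount_scale(self):
        p = PKParameters(fluor=3123.0, ke=0.049, q=8.37e-9)
        base = auc(CY3A, IMM, 0.0, 48.0, mw=CY3A_MW)
        assert p.fluor * base == pytest.approx(
            fluorescence(p, auc(p, IMM, 0.0, 48.0, mw=CY3A_MW)) / 1.0, rel=1e-12
        )


class TestSteadyState:
    def test_value_matches_hand_computation_and_long_ode(self):
        ss = steady_state_amount(CY3A, IMM, mw=CY3A_MW)
        assert ss == pytest.approx(8.37e-9 * 5.3014e6 / 0.049, rel=1e-12)
        long = amount_trajectory_ode(CY3A, IMM, [500.0], mw=CY3A_MW)
        assert long.amounts[-1] == pytest.approx(ss, rel=1e-6)

    def test_linearity_in_bath_concentration(self):
        double = ExposureRegimen(route=Route.IMMERSION, medium_conc_um=20.0)
        assert steady_state_amount(CY3A, double, mw=CY3A_MW) == pytest.approx(
            2 * steady_state_amount(CY3A, IMM, mw=CY3A_MW), rel=1e-12
        )

    def test_no_exchange_and_no_medium(self):
        p = PKParameters(fluor=1.0, ke=0.049, q=0.0)
        assert steady_state_amount(p, IMM, mw=CY3A_MW) == 0.0
        with pytest.raises(ValueError):
            steady_state_amount(CY3A, INJ)


class TestAuc:
    def test_injection_full_integral_is_dose_over_ke(self):
        assert auc(CY3A, INJ, 0.0, math.inf) == pytest.approx(0.5 / 0.049, rel=1e-12)

    def test_cy3a_injection_0_48(self):
        expected = 0.5 * (1 - math.exp(-0.049 * 48)) / 0.049
        got = auc(CY3A, INJ, 0.0, 48.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(9.23, abs=0.01)

    def test_closed_form_matches_fine_trapezoid(self):
        t = np.linspace(0.0, 48.0, 10_001)
        for regimen in (INJ, IMM, COMBO):
            grid = amount_at_time(CY3A, regimen, t, mw=CY3A_MW)
            assert auc(CY3A, regimen, 0.0, 48.0, mw=CY3A_MW) == pytest.approx(
                np.trapezoid(grid, t), rel=1e-4
            )

    def test_interval_additivity(self):
        whole = auc(CY3A, COMBO, 0.0, 48.0, mw=CY3A_MW)
        split = auc(CY3A, COMBO, 0.0, 7.0, mw=CY3A_MW) + auc(CY3A, COMBO, 7.0, 48.0, mw=CY3A_MW)
        assert whole == pytest.approx(split, rel=1e-12)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            auc(CY3A, INJ, 5.0, 5.0)


class TestSerialization:
    def test_flat_config_roundtrip(self, tmp_path):
        cfg = regimen_params_to_config(COMBO, CY3A)
        for name in ("c.json", "c.yaml"):
            path = tmp_path / name
            write_config(path, cfg)
            regimen, params = regimen_params_from_config(read_config(path))
            assert regimen == COMBO
            assert params == CY3A

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"route": "immersion"},  # no concentration, no dose
            {"route": "immersion", "medium_conc_um": 10, "dose_mg_per_kg": 2},
            {"route": "combination", "medium_conc_um": 10},
            {"route": "PC", "dose_mg_per_kg": 2, "sampling_times_h": (3.0, 1.0)},
        ],
    )
    def test_invalid_regimens_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExposureRegimen(**kwargs)

    def test_invalid_parameters_rejected(self):
        for bad in ({"fluor": 0}, {"ke": 0}, {"q": -1e-9}):
            kwargs = {"fluor": 1.0, "ke": 0.1, "q": 1e-9, **bad}
            with pytest.raises(ValueError):
                PKParameters(**kwargs)
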