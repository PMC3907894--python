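"""Exponential decay fitting, model selection and trace characterization."""

import json

import numpy as np
import pytest
from scipy.optimize import brentq

import meltkin as mk
from meltkin import FitError, TraceDataError
from meltkin.kinetics import build_rate_table
from meltkin.lumry import _h, _suspended_aggregate

from conftest import make_decay

# Printed rate pairs used as generating parameters throughout (min^-1):
# fast/slow for the low-detergent double regime, single for high detergent.
K_FAST, K_SLOW = 2.242, 0.340
K_SINGLE = 1.582


class TestSingleExponential:
    def test_noiseless_recovery_of_printed_rate(self):
        fit = mk.fit_single_exponential(make_decay([(K_SINGLE, 1.0)]))
        assert fit.k_u1 == pytest.approx(K_SINGLE, rel=1e-6)
        assert fit.model == "single"

    def test_offset_and_amplitude_recovered(self):
        fit = mk.fit_single_exponential(make_decay([(1.0, -8000.0)], y_inf=-1000.0))
        assert fit.a1 == pytest.approx(-8000.0, rel=1e-6)
        assert fit.y_inf == pytest.approx(-1000.0, rel=1e-6)

    def test_constant_trace_flagged(self):
        trace = make_decay([], y_inf=0.5)
        fit = mk.fit_single_exponential(trace)
        assert "negligible_amplitude" in fit.warnings

    def test_time_rescaling_halves_rate(self):
        trace = make_decay([(K_SINGLE, 1.0)])
        stretched = mk.KineticTrace(
            time_s=trace.time_s * 2, signal=trace.signal,
            signal_kind=trace.signal_kind, condition=trace.condition,
        )
        fit = mk.fit_single_exponential(stretched)
        assert fit.k_u1 == pytest.approx(K_SINGLE / 2, rel=1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(TraceDataError):
            mk.fit_single_exponential(make_decay([(1.0, 1.0)], duration_min=0.1))


class TestDoubleExponential:
    def test_noiseless_recovery_of_printed_rate_pair(self):
        fit = mk.fit_double_exponential(
            make_decay([(K_FAST, 0.8), (K_SLOW, 0.2)])
        )
        assert fit.model == "double"
        assert fit.k_u1 == pytest.approx(K_FAST, rel=1e-4)
        assert fit.k_u2 == pytest.approx(K_SLOW, rel=1e-4)
        assert fit.k_u1 >= fit.k_u2
        assert fit.a1 == pytest.approx(0.8, rel=1e-4)
        assert fit.a2 == pytest.approx(0.2, rel=1e-4)

    def test_single_generated_data_degenerates(self):
        fit = mk.fit_double_exponential(make_decay([(K_SINGLE, 1.0)]))
        degenerate = (
            "rate_collapse" in fit.warnings
            or fit.k_u1 / (fit.k_u2 or fit.k_u1) < 1.5
            or min(abs(fit.a1), abs(fit.a2 or 0.0)) < 1e-3
        )
        assert degenerate

    def test_affine_signal_map_leaves_rates_unchanged(self):
        trace = make_decay([(K_FAST, 0.8), (K_SLOW, 0.2)])
        mapped = mk.KineticTrace(
            time_s=trace.time_s, signal=-8000.0 * trace.signal - 1000.0,
            signal_kind=trace.signal_kind, condition=trace.condition,
        )
        fit = mk.fit_double_exponential(mapped)
        assert fit.k_u1 == pytest.approx(K_FAST, rel=1e-4)
        assert fit.k_u2 == pytest.approx(K_SLOW, rel=1e-4)

    def test_noisy_monte_carlo_median_error_under_five_percent(self):
        errors = []
        for seed in range(100):
            trace = make_decay(
                [(K_FAST, 0.8), (K_SLOW, 0.2)], noise=0.02, seed=seed
            )
            fit = mk.fit_double_exponential(trace)
            errors.append(abs(fit.k_u1 - K_FAST) / K_FAST)
        assert np.median(errors) < 0.05


class TestSelectModel:
    def test_separated_biexponential_selected_double(self):
        trace = make_decay([(K_FAST, 0.8), (K_SLOW, 0.2)], noise=0.01, seed=3)
        assert mk.select_model(trace).model == "double"

    def test_pure_single_selected_single(self):
        trace = make_decay([(K_SINGLE, 1.0)], noise=0.01, seed=3)
        assert mk.select_model(trace).model == "single"

    def test_close_rates_fail_separation_criterion(self):
        trace = make_decay([(1.5, 0.5), (1.0, 0.5)], noise=0.01, seed=3)
        assert mk.select_model(trace).model == "single"

    def test_override_forces_model(self):
        trace = make_decay([(K_FAST, 0.8), (K_SLOW, 0.2)])
        assert mk.select_model(trace, override="single").model == "single"
        assert mk.select_model(trace, override="double").model == "double"

    def test_invalid_override_rejected(self):
        with pytest.raises(ValueError):
            mk.select_model(make_decay([(1.0, 1.0)]), override="triple")


class TestRateTable:
    def _results(self, temps, variant="WT", ldao=5.0, model="double"):
        out = []
        for temp in temps:
            cond = mk.Condition(variant, ldao, 5.0, temp)
            kwargs = dict(model=model, k_u1=2.0, a1=0.8, y_inf=0.0)
            if model == "double":
                kwargs.update(k_u2=0.3, a2=0.2)
            out.append((cond, mk.ExpFitResult(**kwargs)))
        return out

    def test_one_row_per_condition(self):
        table = build_rate_table(self._results([65, 70, 75, 80, 85, 90, 95]))
        assert len(table) == 7
        assert table["lpr"].iloc[0] == pytest.approx(1000.0)

    def test_single_fits_leave_slow_rate_absent(self):
        table = build_rate_table(self._results([80], model="single"))
        assert table["ku2_per_min"].isna().all()

    def test_empty_input_is_valid_empty_table(self):
        table = build_rate_table([])
        assert len(table) == 0
        json.loads(table.to_json(orient="records"))  # still serializable

    def test_duplicate_condition_rejected(self):
        rows = self._results([80]) + self._results([80])
        with pytest.raises(TraceDataError):
            build_rate_table(rows)

    def test_json_round_trip_lossless(self):
        table = build_rate_table(self._results([65, 80, 95]))
        back = json.loads(table.to_json(orient="records"))
        for row, rec in zip(table.itertuples(index=False), back):
            assert rec["ku1_per_min"] == row.ku1_per_min
            assert rec["temp_C"] == row.temp_C


def _pmt_trace(k1, k2, k_settle, s_gain=300.0, duration_min=15.0, dt_s=1.0):
    cond = mk.Condition("WT", 5.0, 5.0, 80.0)
    t_s = np.arange(0.0, duration_min * 60 + 0.5 * dt_s, dt_s)
    a_s = _suspended_aggregate(k1, k2, k_settle, t_s / 60.0)
    return mk.KineticTrace(
        time_s=t_s, signal=s_gain * a_s, signal_kind="pmt_voltage",
        condition=cond,
    )


class TestAggregationPeak:
    def test_settling_disabled_gives_monotone_no_peak(self):
        sig = mk.detect_aggregation_peak(_pmt_trace(2.0, 0.4, 0.0))
        assert sig.no_peak

    def test_flat_trace_no_peak(self):
        cond = mk.Condition("WT", 5.0, 5.0, 80.0)
        t = np.arange(60.0)
        trace = mk.KineticTrace(t, np.full(60, 350.0), "pmt_voltage", cond)
        assert mk.detect_aggregation_peak(trace).no_peak

    def test_peak_matches_analytic_stationarity_condition(self):
        # At the PMT maximum, production balances settling:
        # k2 * f_N*(t*) = k_settle * A_s(t*). Solve that condition with an
        # independent root finder and require detection within one sample.
        k1, k2, ks = 2.242, 0.340, 0.8

        def balance(t_min):
            f_nstar = k1 * float(_h(k1, k2, np.array([t_min]))[0])
            a_s = float(_suspended_aggregate(k1, k2, ks, np.array([t_min]))[0])
            return k2 * f_nstar - ks * a_s

        t_star_min = brentq(balance, 0.2, 14.0)
        sig = mk.detect_aggregation_peak(_pmt_trace(k1, k2, ks))
        assert not sig.no_peak
        assert abs(sig.t_peak_s - t_star_min * 60.0) <= 1.0
        assert sig.settle_rate_per_min > 0


class TestAnisotropy:
    def test_simulated_drop_then_rise_levels(self):
        params = mk.wt_params(5.0)  # r_n=0.14, r_u=0.07, r_d=0.16
        out = mk.simulate_isothermal(params, 80.0, 20.0)
        sig = mk.characterize_anisotropy(out["anisotropy"])
        assert sig.r_initial == pytest.approx(0.14, abs=0.01)
        assert 0.07 < sig.r_min < 0.14
        assert sig.r_final == pytest.approx(0.16, abs=0.01)
        assert out["anisotropy"].time_s[0] <= sig.t_min_s <= out["anisotropy"].time_s[-1]

    def test_constant_trace(self):
        cond = mk.Condition("WT", 5.0, 5.0, 80.0)
        trace = mk.KineticTrace(
            np.arange(30.0), np.full(30, 0.14), "anisotropy", cond
        )
        sig = mk.characterize_anisotropy(trace)
        assert sig.r_initial == sig.r_min == sig.r_final == 0.14

    def test_out_of_range_rejected_at_construction(self):
        cond = mk.Condition("WT", 5.0, 5.0, 80.0)
        with pytest.raises(TraceDataError):
            mk.KineticTrace(
                np.arange(30.0), np.full(30, 0.6), "anisotropy", cond
            )


def test_both_fits_failing_raises_fit_error():
    # two points only -> both fitters refuse via the length precondition
    cond = mk.Condition("WT", 5.0, 5.0, 80.0)
    trace = mk.KineticTrace(
        np.arange(12.0), np.linspace(1, 0, 12), "fraction_unfolded", cond
    )
    # 12 points: single can run, double (needs 20) cannot -> falls back cleanly
    assert mk.select_model(trace).model == "single"
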