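"""Forward simulator: closed forms vs ODE oracle, observables, protocols."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import meltkin as mk
from meltkin.lumry import (
    StudyConfig,
    _suspended_aggregate,
    anchored_pre_exponential,
)

T_GRID = np.linspace(0.0, 12.0, 241)  # minutes


def ode_oracle(k1, k2, k_settle, t_grid):
    """Independent stiff integration of the full scheme (N, N*, D, A_s)."""

    def rhs(_, y):
        f_n, f_ns, f_d, a_s = y
        return [
            -k1 * f_n,
            k1 * f_n - k2 * f_ns,
            k2 * f_ns,
            k2 * f_ns - k_settle * a_s,
        ]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [1.0, 0.0, 0.0, 0.0], t_eval=t_grid,
        rtol=1e-11, atol=1e-13, method="LSODA",
    )
    return sol.y


class TestRateAtTemperature:
    def test_zero_activation_energy_is_flat(self):
        for temp in (4.0, 37.0, 95.0):
            assert mk.rate_at_temperature(3.0, 0.0, temp) == pytest.approx(3.0)

    def test_anchoring_round_trip(self):
        a = anchored_pre_exponential(2.242, 16.54, 80.0)
        assert mk.rate_at_temperature(a, 16.54, 80.0) == pytest.approx(2.242, rel=1e-12)

    def test_arrhenius_fit_inverts_the_generator(self):
        a = anchored_pre_exponential(2.242, 16.54, 80.0)
        pts = [(t, mk.rate_at_temperature(a, 16.54, t)) for t in range(65, 100, 5)]
        fit = mk.arrhenius_fit(pts)
        assert fit.eact_kcal_mol == pytest.approx(16.54, abs=1e-9)
        assert np.exp(fit.ln_a) == pytest.approx(a, rel=1e-6)

    def test_negative_pre_exponential_rejected(self):
        with pytest.raises(ValueError):
            mk.rate_at_temperature(-1.0, 16.0, 80.0)


class TestSpeciesTrajectories:
    def test_initial_and_absorbing_states(self):
        traj = mk.species_trajectories(2.0, 0.4, np.array([0.0, 1e4]))
        np.testing.assert_allclose(
            [traj.f_n[0], traj.f_nstar[0], traj.f_d[0]], [1.0, 0.0, 0.0], atol=1e-15
        )
        np.testing.assert_allclose(
            [traj.f_n[-1], traj.f_nstar[-1], traj.f_d[-1]], [0.0, 0.0, 1.0], atol=1e-12
        )

    def test_equal_rates_confluent_limit(self):
        traj = mk.species_trajectories(1.0, 1.0, np.array([1.0]))
        assert traj.f_nstar[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize(
        "k1, k2",
        [(2.242, 0.340), (0.34, 2.242), (1.0, 1.0 + 1e-9), (5.0, 50.0),
         (0.01, 0.8), (3.0, 3.0)],
    )
    def test_agreement_with_ode_oracle(self, k1, k2):
        traj = mk.species_trajectories(k1, k2, T_GRID)
        f_n, f_ns, f_d, _ = ode_oracle(k1, k2, 0.0, T_GRID)
        np.testing.assert_allclose(traj.f_n, f_n, atol=1e-8)
        np.testing.assert_allclose(traj.f_nstar, f_ns, atol=1e-8)
        np.testing.assert_allclose(traj.f_d, f_d, atol=1e-8)

    def test_mass_conservation_and_monotonicity(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            k1, k2 = rng.uniform(0.01, 20.0, 2)
            traj = mk.species_trajectories(k1, k2, T_GRID)
            total = traj.f_n + traj.f_nstar + traj.f_d
            np.testing.assert_allclose(total, 1.0, atol=1e-9)
            assert np.all(np.diff(traj.f_d) >= -1e-12)
            assert np.all(np.diff(traj.f_n) <= 1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mk.species_trajectories(-1.0, 0.4, T_GRID)


class TestSuspendedAggregate:
    @pytest.mark.parametrize(
        "k1, k2, ks",
        [(2.242, 0.34, 0.8), (2.0, 50.0, 0.5), (1.0, 1.0, 0.7),
         (0.5, 0.5000001, 0.5), (2.0, 0.4, 0.0)],
    )
    def test_agreement_with_ode_oracle(self, k1, k2, ks):
        a_s = _suspended_aggregate(k1, k2, ks, T_GRID)
        _, _, _, oracle = ode_oracle(k1, k2, ks, T_GRID)
        np.testing.assert_allclose(a_s, oracle, atol=1e-8)

    def test_no_settling_accumulates_everything(self):
        # with k_settle = 0 the pool equals f_D and tends to 1
        long_t = np.linspace(0.0, 200.0, 101)
        a_s = _suspended_aggregate(2.0, 0.4, 0.0, long_t)
        assert np.all(np.diff(a_s) >= -1e-14)
        assert a_s[-1] == pytest.approx(1.0, abs=1e-10)


class TestSimulateIsothermal:
    def test_silent_intermediate_yields_pure_slow_exponential(self):
        # me_nstar == me_n hides the first step: the CD decay carries k2 only
        params = mk.wt_params(5.0, me_nstar=-9000.0, noise_sigma=0.0)
        k1, k2 = params.rates_at(80.0)
        out = mk.simulate_isothermal(params, 80.0, 20.0)
        # discard the burn-in of the intermediate (several fast lifetimes)
        settled = mk.trim_dead_time(out["me215"], 180.0)
        fit = mk.fit_single_exponential(settled)
        assert fit.k_u1 == pytest.approx(k2, rel=5e-3)

    def test_fast_second_step_collapses_to_rate_limiting_first(self):
        params = mk.wt_params(5.0, noise_sigma=0.0)
        k1, _ = params.rates_at(80.0)
        fast = mk.LumryParams(
            a1=params.a1, ea1=params.ea1,
            a2=anchored_pre_exponential(k1 * 2000.0, params.ea2, 80.0),
            ea2=params.ea2, me_nstar=params.me_nstar,
        )
        out = mk.simulate_isothermal(fast, 80.0, 10.0)
        fit = mk.fit_single_exponential(out["me215"])
        assert fit.k_u1 == pytest.approx(k1, rel=1e-3)

    def test_pmt_monotone_and_complete_without_settling(self):
        params = mk.wt_params(5.0, k_settle=0.0, noise_sigma=0.0, s_gain=300.0)
        out = mk.simulate_isothermal(params, 80.0, 120.0, dt_s=10.0)
        pmt = out["pmt"].signal
        assert np.all(np.diff(pmt) >= -1e-9)
        assert pmt[-1] == pytest.approx(300.0, rel=1e-4)  # s_gain * f_D(inf)

    def test_seeded_runs_bit_reproducible(self):
        params = mk.wt_params(5.0, noise_sigma=0.02, seed=7)
        a = mk.simulate_isothermal(params, 80.0, 5.0)
        b = mk.simulate_isothermal(params, 80.0, 5.0)
        for channel in ("me215", "anisotropy", "pmt"):
            np.testing.assert_array_equal(a[channel].signal, b[channel].signal)


class TestSimulateTscan:
    def test_constant_rate_closed_form(self):
        # ea1 = 0: f_N(T) = exp(-k (T - T_start) / beta) exactly
        k = 0.05
        params = mk.LumryParams(a1=k, ea1=0.0, a2=1.0, ea2=0.0, noise_sigma=0.0)
        scan = mk.simulate_tscan(params, 20.0, 95.0, ramp_C_per_min=1.0)
        f_n = (scan.signal - params.me_d) / (params.me_n - params.me_d)
        expected = np.exp(-k * (scan.temperature_C - 20.0) / 1.0)
        np.testing.assert_allclose(f_n, expected, atol=1e-7)

    def test_midpoint_satisfies_integral_condition(self):
        # at the apparent midpoint, (1/beta) * int k1 dT = ln 2
        params = mk.wt_params(13.0, noise_sigma=0.0)
        beta = 1.0
        tm = mk.apparent_midpoint(params, 20.0, 95.0, beta)
        from scipy.integrate import quad

        integral, _ = quad(
            lambda T: mk.rate_at_temperature(params.a1, params.ea1, T), 20.0, tm
        )
        assert integral / beta == pytest.approx(np.log(2.0), rel=1e-4)

    def test_faster_ramp_raises_apparent_midpoint(self):
        params = mk.wt_params(13.0, noise_sigma=0.0)
        tm1 = mk.apparent_midpoint(params, 20.0, 95.0, 1.0)
        tm2 = mk.apparent_midpoint(params, 20.0, 95.0, 2.0)
        assert tm2 > tm1

    def test_higher_activation_energy_raises_apparent_midpoint(self):
        low = mk.wt_params(13.0)
        k_ref = low.rates_at(80.0)[0]
        high = mk.LumryParams(
            a1=anchored_pre_exponential(k_ref, 25.0, 80.0), ea1=25.0,
            a2=low.a2, ea2=low.ea2,
        )
        assert (
            mk.apparent_midpoint(high, 20.0, 95.0, 1.0)
            > mk.apparent_midpoint(low, 20.0, 95.0, 1.0)
        )


class TestSimulateProtocol:
    def test_heat_cool_reheat_shows_no_fast_phase_recovery(self):
        params = mk.wt_params(65.0, noise_sigma=0.0)
        trace = mk.simulate_protocol(params, [(80.0, 2.0), (4.0, 10.0), (80.0, 10.0)])
        seg = trace.extra["segment"]
        f_n = trace.extra["f_n"]
        # the native pool never re-forms: at the start of the reheat it is
        # exactly what survived the first heat, far below the initial 1.0
        reheat_start = np.nonzero(seg == 2)[0][0]
        assert f_n[reheat_start] < f_n[0]
        assert np.all(np.diff(f_n) <= 1e-12)
        # and the reheat decay is dominated by the slow (aggregation) phase:
        # the native pool entering the reheat is a small remnant
        assert f_n[reheat_start] < 0.15

    def test_cold_segment_is_static(self):
        # a steep temperature dependence makes the 4 degC rates negligible
        params = mk.LumryParams(
            a1=anchored_pre_exponential(2.242, 30.0, 80.0), ea1=30.0,
            a2=anchored_pre_exponential(0.34, 30.0, 80.0), ea2=30.0,
        )
        trace = mk.simulate_protocol(params, [(4.0, 10.0)])
        assert np.ptp(trace.signal) < 1e-3 * abs(params.me_n - params.me_d)
        assert trace.extra["f_n"][-1] == pytest.approx(1.0, abs=1e-3)

    def test_single_segment_matches_isothermal(self):
        params = mk.wt_params(5.0, noise_sigma=0.0)
        proto = mk.simulate_protocol(params, [(80.0, 5.0)])
        iso = mk.simulate_isothermal(params, 80.0, 5.0)["me215"]
        np.testing.assert_allclose(proto.signal, iso.signal, atol=1e-9)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            mk.simulate_protocol(mk.wt_params(5.0), [])


class TestStudyDataset:
    def test_counts_and_manifest(self, tmp_path):
        config = StudyConfig(
            variants=("WT",), ldao_mM=(5.0, 80.0), temperatures_C=(80.0, 95.0),
            duration_min=5.0,
        )
        out = mk.generate_study_dataset(config, seed=3, out_dir=tmp_path / "d")
        files = sorted(p.name for p in Path(out).glob("*.csv"))
        assert len([f for f in files if f.startswith("iso_")]) == 4
        assert len([f for f in files if f.startswith("tscan_")]) == 2
        manifest = json.loads((Path(out) / "manifest.json").read_text())
        assert len(manifest["traces"]) == 4
        assert {t["regime"] for t in manifest["traces"]} == {"double", "single"}

    def test_same_seed_byte_identical(self, tmp_path):
        config = StudyConfig(
            variants=("C0",), ldao_mM=(13.0,), temperatures_C=(75.0, 90.0),
            duration_min=3.0,
        )
        out1 = mk.generate_study_dataset(config, seed=11, out_dir=tmp_path / "a")
        out2 = mk.generate_study_dataset(config, seed=11, out_dir=tmp_path / "b")
        for p1 in sorted(Path(out1).iterdir()):
            p2 = Path(out2) / p1.name
            assert p1.read_bytes() == p2.read_bytes()

    def test_manifest_rates_round_trip_through_fitters(self, tmp_path):
        config = StudyConfig(
            variants=("WT",), ldao_mM=(5.0,), temperatures_C=(80.0,),
            duration_min=15.0, noise_sigma=0.02,
        )
        out = mk.generate_study_dataset(config, seed=5, out_dir=tmp_path / "d")
        manifest = json.loads((Path(out) / "manifest.json").read_text())
        entry = manifest["traces"][0]
        trace = mk.read_trace(Path(out) / entry["file"], kind="kinetic")
        fit = mk.select_model(trace)
        assert fit.k_u1 == pytest.approx(entry["k1_per_min"], rel=0.05)
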