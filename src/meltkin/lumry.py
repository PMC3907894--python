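"""Forward simulator of irreversible sequential unfolding, N -> N* -> D.

The scheme is a Lumry-Eyring variant in which *both* steps are irreversible:
the native barrel N converts to a kinetically trapped, partially structured
intermediate N* (rate k1), which aggregates to D (rate k2). Each rate obeys
an Arrhenius law, k(T) = A exp(-Ea / (R T)). The conventional high-temperature
pseudo-two-state N -> D regime is not a separate scheme here: it emerges
whenever k2 >> k1, because the intermediate never accumulates.

Observables are composed linearly from the species populations:

* mean residue ellipticity  ME(t) = me_n f_N + me_nstar f_N* + me_d f_D
* anisotropy                r(t)  = r_n f_N + r_u f_N* + r_d f_D
* light scattering (PMT)    follows the suspended-aggregate pool A_s with
  dA_s/dt = k2 f_N* - k_settle A_s  — aggregates scatter while suspended and
  stop contributing as they settle out of the beam, which reproduces the
  characteristic rise-then-fall of the PMT voltage.

Species fractions use the exact sequential-first-order closed forms; the
suspended-aggregate pool is analytic except in near-degenerate rate corners,
where a stiff ODE integration takes over.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp
from scipy.special import exprel

from .constants import R_KCAL, celsius_to_kelvin
from .errors import TraceDataError
from .traces import Condition, KineticTrace, ThermalScan, write_trace

__all__ = [
    "LumryParams", "SpeciesTrajectory", "rate_at_temperature",
    "anchored_pre_exponential", "species_trajectories", "simulate_isothermal",
    "simulate_tscan", "apparent_midpoint", "simulate_protocol",
    "generate_study_dataset", "wt_params", "c0_params", "default_study_config",
    "STUDY_LDAO_MM", "STUDY_TEMPERATURES_C",
]


def rate_at_temperature(a: float, ea: float, temperature_C: float) -> float:
    """Arrhenius rate ``a * exp(-ea / (R T))`` in min^-1.

    ``a`` is the pre-exponential (min^-1), ``ea`` the activation energy
    (kcal/mol), temperature in Celsius.
    """
    if a < 0:
        raise ValueError("pre-exponential must be >= 0")
    t_k = celsius_to_kelvin(temperature_C)
    if np.any(np.asarray(t_k) <= 0):
        raise ValueError("temperature must exceed absolute zero")
    return a * np.exp(-ea / (R_KCAL * t_k))


def anchored_pre_exponential(k_ref: float, ea: float, temp_ref_C: float) -> float:
    """Pre-exponential such that the Arrhenius law passes through (temp_ref, k_ref)."""
    if k_ref <= 0:
        raise ValueError("reference rate must be positive")
    return k_ref * np.exp(ea / (R_KCAL * celsius_to_kelvin(temp_ref_C)))


@dataclass(frozen=True)
class LumryParams:
    """Full parameterization of the N -> N* -> D forward model.

    Rates: ``a1``/``ea1`` for N -> N*, ``a2``/``ea2`` for N* -> D
    (pre-exponentials in min^-1, activation energies kcal/mol), ``k_settle``
    the first-order settling rate of suspended aggregates (min^-1).

    Signals: species ellipticities ``me_n``, ``me_nstar``, ``me_d``
    (deg cm^2 dmol^-1), species anisotropies ``r_n``, ``r_u``, ``r_d``,
    and ``s_gain`` (PMT volts per unit suspended aggregate).

    ``noise_sigma`` is the additive Gaussian noise level as a fraction of
    each channel's dynamic range; ``seed`` makes every simulated trace
    bit-reproducible.
    """

    a1: float
    ea1: float
    a2: float
    ea2: float
    k_settle: float = 0.5
    me_n: float = -9000.0
    me_nstar: float = -5400.0
    me_d: float = -1000.0
    r_n: float = 0.14
    r_u: float = 0.07
    r_d: float = 0.16
    s_gain: float = 300.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("a1", "a2", "k_settle", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("r_n", "r_u", "r_d"):
            r = getattr(self, name)
            if not -0.2 <= r <= 0.4:
                raise ValueError(f"{name}={r} outside the physical range [-0.2, 0.4]")

    def rates_at(self, temperature_C: float) -> tuple[float, float]:
        """(k1, k2) in min^-1 at the given temperature."""
        return (
            rate_at_temperature(self.a1, self.ea1, temperature_C),
            rate_at_temperature(self.a2, self.ea2, temperature_C),
        )


@dataclass
class SpeciesTrajectory:
    """Species fractions (and suspended aggregate) over a time grid (minutes)."""

    time_min: np.ndarray
    f_n: np.ndarray
    f_nstar: np.ndarray
    f_d: np.ndarray
    a_s: np.ndarray | None = None


def _h(a, b, t):
    """Solution of y' + b y = exp(-a t), y(0) = 0; stable as b -> a.

    Equals (exp(-a t) - exp(-b t)) / (b - a), which is symmetric in (a, b);
    factoring the decay of the smaller rate and using exprel keeps it stable
    both at the removable singularity b = a and for widely separated rates.
    """
    t = np.asarray(t, dtype=float)
    small, large = min(a, b), max(a, b)
    return np.exp(-small * t) * t * exprel(-(large - small) * t)


def species_trajectories(k1: float, k2: float, time_min) -> SpeciesTrajectory:
    """Closed-form species fractions of N -> N* -> D from a pure-N start.

    f_N = exp(-k1 t); f_N* = k1 (exp(-k1 t) - exp(-k2 t)) / (k2 - k1) with the
    confluent limit k1 t exp(-k1 t) as k2 -> k1; f_D closes the mass balance.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("rates must be >= 0")
    t = np.asarray(time_min, dtype=float)
    f_n = np.exp(-k1 * t)
    f_nstar = k1 * _h(k1, k2, t)
    f_d = 1.0 - f_n - f_nstar
    return SpeciesTrajectory(time_min=t, f_n=f_n, f_nstar=f_nstar, f_d=f_d)


def _suspended_aggregate(k1, k2, k_settle, t):
    """Suspended-aggregate pool A_s(t): dA_s/dt = k2 f_N* - k_settle A_s, A_s(0)=0."""
    t = np.asarray(t, dtype=float)
    if k_settle == 0.0:
        # without settling, everything that ever aggregated stays suspended
        traj = species_trajectories(k1, k2, t)
        return traj.f_d
    scale = max(k1, k2, k_settle)
    if scale > 0 and abs(k2 - k1) > 1e-6 * scale:
        return k2 * k1 / (k2 - k1) * (_h(k1, k_settle, t) - _h(k2, k_settle, t))
    # near-degenerate k1 ~ k2: integrate the forcing numerically
    def rhs(tt, y):
        f_nstar = k1 * float(_h(k1, k2, np.array([tt]))[0])
        return [k2 * f_nstar - k_settle * y[0]]

    sol = solve_ivp(
        rhs, (0.0, float(t[-1]) if t.size else 0.0), [0.0],
        t_eval=t, rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return sol.y[0]


def _spawn_rngs(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _add_noise(signal, sigma_frac, rng):
    if sigma_frac == 0.0:
        return signal
    span = float(np.ptp(signal))
    if span == 0.0:
        return signal
    return signal + rng.normal(0.0, sigma_frac * span, size=signal.shape)


_DEFAULT_CONDITION = Condition(variant="WT", detergent_mM=65.0, protein_uM=5.0)


def simulate_isothermal(
    params: LumryParams,
    temperature_C: float,
    duration_min: float,
    dt_s: float = 1.0,
    condition: Condition | None = None,
    dead_time_s: float = 0.0,
) -> dict[str, KineticTrace]:
    """Simulate one isothermal run; returns ME215, anisotropy and PMT traces.

    Sampling starts at ``dead_time_s`` (the instrument's unobserved initial
    interval; species still evolve from t = 0). Noise per channel is Gaussian
    with sigma = ``noise_sigma`` x that channel's noiseless dynamic range,
    drawn from independent streams spawned from ``params.seed``; repeated
    calls with the same parameters are bit-identical.
    """
    if duration_min <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")
    if condition is None:
        condition = replace(_DEFAULT_CONDITION, temperature_C=temperature_C)
    k1, k2 = params.rates_at(temperature_C)
    time_s = np.arange(dead_time_s, duration_min * 60.0 + 0.5 * dt_s, dt_s)
    t_min = time_s / 60.0
    traj = species_trajectories(k1, k2, t_min)
    a_s = _suspended_aggregate(k1, k2, params.k_settle, t_min)

    me = (
        params.me_n * traj.f_n
        + params.me_nstar * traj.f_nstar
        + params.me_d * traj.f_d
    )
    aniso = (
        params.r_n * traj.f_n + params.r_u * traj.f_nstar + params.r_d * traj.f_d
    )
    pmt = params.s_gain * a_s

    rng_me, rng_an, rng_pmt = _spawn_rngs(params.seed, 3)
    me = _add_noise(me, params.noise_sigma, rng_me)
    aniso = np.clip(
        _add_noise(aniso, params.noise_sigma, rng_an), -0.2, 0.4
    )
    pmt = _add_noise(pmt, params.noise_sigma, rng_pmt)

    species = {"f_n": traj.f_n, "f_nstar": traj.f_nstar, "f_d": traj.f_d}
    return {
        "me215": KineticTrace(
            time_s=time_s, signal=me, signal_kind="ME215",
            condition=condition, dead_time_s=dead_time_s, extra=dict(species),
        ),
        "anisotropy": KineticTrace(
            time_s=time_s, signal=aniso, signal_kind="anisotropy",
            condition=condition, dead_time_s=dead_time_s,
        ),
        "pmt": KineticTrace(
            time_s=time_s, signal=pmt, signal_kind="pmt_voltage",
            condition=condition, dead_time_s=dead_time_s,
            extra={"a_s": a_s},
        ),
    }


def _native_survival(params, t_start_C, t_end_C, ramp_C_per_min, step_C=0.1):
    """Fine grid of temperature and surviving native fraction along a ramp.

    f_N(T) = exp(-(1/beta) ∫ k1(T') dT'), integral by Simpson quadrature.
    """
    grid = np.arange(t_start_C, t_end_C + 0.5 * step_C, step_C)
    k1 = rate_at_temperature(params.a1, params.ea1, grid)
    integral = cumulative_simpson(k1, x=grid, initial=0.0)
    return grid, np.exp(-integral / ramp_C_per_min)


def simulate_tscan(
    params: LumryParams,
    t_start_C: float = 4.0,
    t_end_C: float = 95.0,
    ramp_C_per_min: float = 1.0,
    step_C: float = 0.5,
    condition: Condition | None = None,
    include_intermediate: bool = False,
) -> ThermalScan:
    """Simulate a temperature-ramp CD melt under the irreversible scheme.

    The surviving native fraction obeys
    f_N(T) = exp(-(1/beta) ∫ k1(T') dT') (Simpson quadrature on a 0.1 °C
    grid). By default the intermediate stage is folded into the final state
    (signal = me_n f_N + me_d (1 - f_N)); ``include_intermediate=True``
    integrates all three species along the ramp instead.
    """
    if t_end_C <= t_start_C:
        raise ValueError("t_end must exceed t_start")
    if ramp_C_per_min <= 0:
        raise ValueError("ramp rate must be positive")
    if condition is None:
        condition = _DEFAULT_CONDITION
    temp = np.arange(t_start_C, t_end_C + 0.5 * step_C, step_C)

    if include_intermediate:
        def rhs(T, y):
            k1 = rate_at_temperature(params.a1, params.ea1, T)
            k2 = rate_at_temperature(params.a2, params.ea2, T)
            f_n, f_ns = y
            return [
                -k1 * f_n / ramp_C_per_min,
                (k1 * f_n - k2 * f_ns) / ramp_C_per_min,
            ]

        sol = solve_ivp(
            rhs, (t_start_C, t_end_C), [1.0, 0.0], t_eval=temp,
            rtol=1e-10, atol=1e-12, method="LSODA",
        )
        f_n, f_ns = sol.y
        f_d = 1.0 - f_n - f_ns
        signal = params.me_n * f_n + params.me_nstar * f_ns + params.me_d * f_d
    else:
        grid, surv = _native_survival(params, t_start_C, t_end_C, ramp_C_per_min)
        f_n = np.interp(temp, grid, surv)
        signal = params.me_n * f_n + params.me_d * (1.0 - f_n)

    (rng,) = _spawn_rngs(params.seed, 1)
    signal = _add_noise(signal, params.noise_sigma, rng)
    return ThermalScan(
        temperature_C=temp, signal=signal,
        ramp_C_per_min=ramp_C_per_min, condition=condition,
    )


def apparent_midpoint(
    params: LumryParams,
    t_start_C: float = 4.0,
    t_end_C: float = 95.0,
    ramp_C_per_min: float = 1.0,
) -> float:
    """Apparent ramp midpoint: the temperature at which f_N drops to 1/2.

    A kinetic quantity, not an equilibrium Tm — it shifts up with faster
    ramps and with higher activation energy.
    """
    grid, surv = _native_survival(params, t_start_C, t_end_C, ramp_C_per_min)
    if surv[-1] > 0.5:
        raise TraceDataError("native fraction never reaches 1/2 within the ramp")
    i = int(np.searchsorted(-surv, -0.5))
    if i == 0:
        return float(grid[0])
    # linear interpolation in f_N between bracketing grid points
    f_hi, f_lo = surv[i - 1], surv[i]
    w = (f_hi - 0.5) / (f_hi - f_lo)
    return float(grid[i - 1] + w * (grid[i] - grid[i - 1]))


def simulate_protocol(
    params: LumryParams,
    schedule,
    dt_s: float = 1.0,
    condition: Condition | None = None,
) -> KineticTrace:
    """Simulate a piecewise-isothermal protocol (e.g. heat-cool-reheat).

    ``schedule`` is a list of (temperature_C, duration_min) segments. Rates
    are re-evaluated per segment; the first step is irreversible, so N* never
    reverts to N on cooling. The returned ME215 trace carries the species
    fractions and a per-sample segment index in ``extra``.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if condition is None:
        condition = _DEFAULT_CONDITION

    times, seg_idx = [], []
    f_n_all, f_ns_all, f_d_all = [], [], []
    state = (1.0, 0.0)  # (f_N, f_N*)
    t_offset = 0.0
    for i, (temp_c, duration_min) in enumerate(schedule):
        if duration_min <= 0:
            raise ValueError("segment durations must be positive")
        k1, k2 = params.rates_at(temp_c)
        t_local_s = np.arange(0.0, duration_min * 60.0 + 0.5 * dt_s, dt_s)
        if i > 0:
            t_local_s = t_local_s[1:]  # boundary sample belongs to previous segment
        t_local_min = t_local_s / 60.0
        f_n0, f_ns0 = state
        f_n = f_n0 * np.exp(-k1 * t_local_min)
        f_ns = f_ns0 * np.exp(-k2 * t_local_min) + f_n0 * k1 * _h(
            k1, k2, t_local_min
        )
        f_d = 1.0 - f_n - f_ns
        times.append(t_offset + t_local_s)
        seg_idx.append(np.full(t_local_s.size, i))
        f_n_all.append(f_n)
        f_ns_all.append(f_ns)
        f_d_all.append(f_d)
        # advance state to the exact end of the segment
        end_min = duration_min
        state = (
            f_n0 * np.exp(-k1 * end_min),
            f_ns0 * np.exp(-k2 * end_min)
            + f_n0 * k1 * float(_h(k1, k2, np.array([end_min]))[0]),
        )
        t_offset += duration_min * 60.0

    f_n = np.concatenate(f_n_all)
    f_ns = np.concatenate(f_ns_all)
    f_d = np.concatenate(f_d_all)
    time_s = np.concatenate(times)
    me = params.me_n * f_n + params.me_nstar * f_ns + params.me_d * f_d
    (rng,) = _spawn_rngs(params.seed, 1)
    me = _add_noise(me, params.noise_sigma, rng)
    return KineticTrace(
        time_s=time_s, signal=me, signal_kind="ME215", condition=condition,
        extra={
            "f_n": f_n, "f_nstar": f_ns, "f_d": f_d,
            "segment": np.concatenate(seg_idx).astype(float),
        },
    )


# --- study-design defaults --------------------------------------------------

#: Detergent series of the study design (mM LDAO).
STUDY_LDAO_MM = (5.0, 13.0, 30.0, 65.0, 80.0, 100.0)

#: Isothermal temperature series, °C.
STUDY_TEMPERATURES_C = (65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0)

#: Reference temperature at which rate anchors are specified, °C.
ANCHOR_TEMP_C = 80.0

# Fast-rate anchors k1(80 °C) per (variant, mM LDAO), min^-1, and slow-rate
# anchors k2(80 °C) for the double-phase (low detergent) regime. In the high-
# detergent regime the second step is made much faster than the first
# (k2 >> k1), which collapses the observable kinetics to a single exponential.
_K1_ANCHORS = {
    ("WT", 5.0): 2.242, ("WT", 13.0): 1.766, ("WT", 30.0): 1.352,
    ("WT", 65.0): 1.204, ("WT", 80.0): 0.493, ("WT", 100.0): 0.316,
    ("C0", 5.0): 1.863, ("C0", 13.0): 1.794, ("C0", 30.0): 1.023,
    ("C0", 65.0): 0.831, ("C0", 80.0): 0.520, ("C0", 100.0): 0.776,
}
_K2_ANCHORS = {
    ("WT", 5.0): 0.340, ("WT", 13.0): 0.12, ("WT", 30.0): 0.12,
    ("WT", 65.0): 0.101,
    ("C0", 5.0): 0.176, ("C0", 13.0): 0.12, ("C0", 30.0): 0.12,
    ("C0", 65.0): 0.165,
}

#: Activation energies per variant (kcal/mol) for the first step.
_EA1 = {"WT": 16.54, "C0": 22.64}
#: Activation energy of the second (aggregation) step, kcal/mol.
_EA2 = 15.0
#: Single-exponential regime: k2 anchor (min^-1) at 80 °C, >> every k1.
_K2_FAST_ANCHOR = 50.0
#: Variant-dependent anisotropy of the settled aggregate.
_R_D = {"WT": 0.16, "C0": 0.08}


def _variant_params(variant: str, ldao_mM: float, **overrides) -> LumryParams:
    key = (variant, float(ldao_mM))
    if key not in _K1_ANCHORS:
        raise KeyError(f"no default anchor for {key}")
    ea1 = _EA1[variant]
    k1_ref = _K1_ANCHORS[key]
    k2_ref = _K2_ANCHORS.get(key, _K2_FAST_ANCHOR)
    fields = dict(
        a1=anchored_pre_exponential(k1_ref, ea1, ANCHOR_TEMP_C),
        ea1=ea1,
        a2=anchored_pre_exponential(k2_ref, _EA2, ANCHOR_TEMP_C),
        ea2=_EA2,
        r_d=_R_D[variant],
    )
    fields.update(overrides)
    return LumryParams(**fields)


def wt_params(ldao_mM: float = 5.0, **overrides) -> LumryParams:
    """Default wild-type parameter set, anchored to the study's rate table."""
    return _variant_params("WT", ldao_mM, **overrides)


def c0_params(ldao_mM: float = 5.0, **overrides) -> LumryParams:
    """Default Cys-less (C0) parameter set, anchored to the study's rate table."""
    return _variant_params("C0", ldao_mM, **overrides)


@dataclass(frozen=True)
class StudyConfig:
    """Design of a full synthetic study.

    Defaults mirror the experimental design: two variants x six detergent
    concentrations x seven isothermal temperatures (84 kinetic traces) plus
    one temperature ramp per variant/detergent pair (12 T-scans), at 2%
    channel noise and 1 Hz sampling.
    """

    variants: tuple = ("WT", "C0")
    ldao_mM: tuple = STUDY_LDAO_MM
    temperatures_C: tuple = STUDY_TEMPERATURES_C
    protein_uM: float = 5.0
    duration_min: float = 15.0
    dt_s: float = 1.0
    noise_sigma: float = 0.02
    ramp_C_per_min: float = 1.0
    tscan_start_C: float = 20.0
    tscan_end_C: float = 95.0


def default_study_config() -> StudyConfig:
    return StudyConfig()


def generate_study_dataset(config: StudyConfig | None, seed: int, out_dir) -> Path:
    """Write the full synthetic study to ``out_dir`` and return its path.

    One isothermal ME215 trace per (variant, detergent, temperature) and one
    T-scan per (variant, detergent), in the package CSV dialect, plus a
    ``manifest.json`` recording the ground-truth rates of every trace for
    recovery testing. Fully seeded: the same seed reproduces every file
    byte-for-byte.
    """
    if config is None:
        config = default_study_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"seed": seed, "traces": [], "tscans": []}
    ss = np.random.SeedSequence(seed)
    n_iso = len(config.variants) * len(config.ldao_mM) * len(config.temperatures_C)
    n_scan = len(config.variants) * len(config.ldao_mM)
    children = ss.generate_state(n_iso + n_scan, dtype=np.uint32)

    idx = 0
    for variant in config.variants:
        for ldao in config.ldao_mM:
            for temp in config.temperatures_C:
                params = _variant_params(
                    variant, ldao,
                    noise_sigma=config.noise_sigma,
                    seed=int(children[idx]),
                )
                idx += 1
                condition = Condition(
                    variant=variant, detergent_mM=ldao,
                    protein_uM=config.protein_uM, temperature_C=temp,
                )
                traces = simulate_isothermal(
                    params, temp, config.duration_min, config.dt_s,
                    condition=condition,
                )
                trace = traces["me215"]
                trace.extra = {}  # species ground truth lives in the manifest
                name = f"iso_{variant}_{ldao:g}mM_{temp:g}C.csv"
                write_trace(trace, out / name)
                k1, k2 = params.rates_at(temp)
                manifest["traces"].append(
                    {
                        "file": name, "variant": variant, "ldao_mM": ldao,
                        "temp_C": temp, "k1_per_min": k1, "k2_per_min": k2,
                        "regime": "double" if (variant, ldao) in _K2_ANCHORS
                        else "single",
                        "ea1_kcal_mol": params.ea1,
                        "ea2_kcal_mol": params.ea2,
                        "seed": params.seed,
                    }
                )
    for variant in config.variants:
        for ldao in config.ldao_mM:
            params = _variant_params(
                variant, ldao,
                noise_sigma=config.noise_sigma, seed=int(children[idx]),
            )
            idx += 1
            condition = Condition(
                variant=variant, detergent_mM=ldao, protein_uM=config.protein_uM
            )
            scan = simulate_tscan(
                params, config.tscan_start_C, config.tscan_end_C,
                config.ramp_C_per_min, condition=condition,
            )
            name = f"tscan_{variant}_{ldao:g}mM.csv"
            write_trace(scan, out / name)
            manifest["tscans"].append(
                {
                    "file": name, "variant": variant, "ldao_mM": ldao,
                    "tm_apparent_C": apparent_midpoint(
                        params, config.tscan_start_C, config.tscan_end_C,
                        config.ramp_C_per_min,
                    ),
                    "seed": params.seed,
                }
            )

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
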