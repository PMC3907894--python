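"""Isothermal unfolding-trace fitting and trace characterization.

Isothermal decays are fit to single- or double-exponential models

    y(t) = y_inf + a1 exp(-k_u1 t)
    y(t) = y_inf + a1 exp(-k_u1 t) + a2 exp(-k_u2 t)      (k_u1 >= k_u2)

with rates reported in min^-1 (time is stored in seconds and converted once,
here). The optimizer works in log-rate space, which enforces positivity and
makes the multi-start grid scale-free. Model selection between the two is by
corrected Akaike information (AICc) plus physically-motivated guards on rate
separation and amplitude share, with an explicit override available so a
dataset's published single/double assignment can be reproduced exactly.

The module also extracts summary signatures from the two corroborating
channels of the study design: the photomultiplier-voltage (light scattering)
rise-then-fall of aggregation, and the drop-then-rise of tryptophan
fluorescence anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .errors import FitError, TraceDataError
from .traces import ANISOTROPY_RANGE, Condition, KineticTrace

#: Rate bounds, min^-1.
RATE_BOUNDS = (1e-6, 1e4)

_LOG_BOUNDS = (np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1]))


@dataclass
class ExpFitResult:
    """Fitted exponential decay. Rates in min^-1, sorted fast-first."""

    model: str  # "single" | "double"
    k_u1: float
    a1: float
    y_inf: float
    k_u2: float | None = None
    a2: float | None = None
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0
    aicc: float = float("nan")
    warnings: list = field(default_factory=list)

    def predict(self, time_min):
        t = np.asarray(time_min, dtype=float)
        y = self.y_inf + self.a1 * np.exp(-self.k_u1 * t)
        if self.model == "double":
            y = y + self.a2 * np.exp(-self.k_u2 * t)
        return y


def _aicc(rss, n, p):
    if n - p - 1 <= 0:
        return float("inf")
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _require_trace(trace, min_points, kinds=("ME215", "fraction_unfolded")):
    if trace.signal_kind not in kinds:
        raise TraceDataError(
            f"expected a {kinds} trace, got {trace.signal_kind!r}"
        )
    if len(trace) < min_points:
        raise TraceDataError(
            f"fit requires >= {min_points} points, trace has {len(trace)}"
        )


def _rate_guess(trace) -> float:
    """Crude k guess (min^-1): ln 2 over the observed half-change time."""
    t = trace.time_min
    y = trace.signal
    y0, y1 = y[0], y[-1]
    if y0 == y1:
        return 1.0
    half = 0.5 * (y0 + y1)
    crossing = np.nonzero((y - half) * (y0 - half) <= 0)[0]
    t_half = t[crossing[0]] - t[0] if crossing.size else (t[-1] - t[0]) / 3.0
    t_half = max(t_half, (t[-1] - t[0]) / max(len(y) - 1, 1), 1e-9)
    return float(np.log(2.0) / t_half)


def _boundary_warnings(rates):
    out = []
    for k in rates:
        if k <= RATE_BOUNDS[0] * 1.01 or k >= RATE_BOUNDS[1] * 0.99:
            out.append(f"rate_at_bound:{k:g}")
    return out


def fit_single_exponential(trace: KineticTrace) -> ExpFitResult:
    """Fit ``y = y_inf + a1 exp(-k t)`` to a trimmed kinetic trace."""
    _require_trace(trace, 10)
    t = trace.time_min
    y = trace.signal

    amp0 = y[0] - y[-1]
    span = float(np.ptp(y))
    if span < 1e-12 * max(1.0, abs(float(np.mean(y)))) or span == 0.0:
        return ExpFitResult(
            model="single", k_u1=RATE_BOUNDS[0], a1=0.0,
            y_inf=float(np.mean(y)), rss=float(np.sum((y - np.mean(y)) ** 2)),
            n_points=len(y), warnings=["negligible_amplitude"],
        )

    def residuals(p):
        lnk, a1, y_inf = p
        return y_inf + a1 * np.exp(-np.exp(lnk) * t) - y

    kg = _rate_guess(trace)
    best = None
    diagnostics = {}
    for mult in (1.0, 0.3, 3.0):
        p0 = [np.clip(np.log(kg * mult), *_LOG_BOUNDS), amp0, y[-1]]
        sol = least_squares(
            residuals, p0,
            bounds=([_LOG_BOUNDS[0], -np.inf, -np.inf],
                    [_LOG_BOUNDS[1], np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
        )
        if not sol.success:
            diagnostics[f"start_x{mult}"] = sol.message
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError("single-exponential fit did not converge", diagnostics)

    rss, sol = best
    lnk, a1, y_inf = sol.x
    k = float(np.exp(lnk))
    se = _exp_se(sol, ["ln_k_u1", "a1", "y_inf"])
    se["k_u1"] = k * se.pop("ln_k_u1", float("nan"))
    warnings = _boundary_warnings([k])
    if abs(a1) < 0.01 * span:
        warnings.append("negligible_amplitude")
    return ExpFitResult(
        model="single", k_u1=k, a1=float(a1), y_inf=float(y_inf),
        se=se, rss=rss, n_points=len(y), aicc=_aicc(rss, len(y), 3),
        warnings=warnings,
    )


def fit_double_exponential(trace: KineticTrace) -> ExpFitResult:
    """Fit a biexponential decay; rates returned sorted fast-first.

    Multi-start over log-spaced rate pairs around the single-rate guess. If
    the two rates collapse (ratio < 1.05 at the optimum) the fit is
    degenerate: the single-exponential result is returned instead, carrying a
    ``rate_collapse`` warning.
    """
    _require_trace(trace, 20)
    t = trace.time_min
    y = trace.signal
    amp0 = y[0] - y[-1]

    def residuals(p):
        lnk1, lnk2, a1, a2, y_inf = p
        return (
            y_inf
            + a1 * np.exp(-np.exp(lnk1) * t)
            + a2 * np.exp(-np.exp(lnk2) * t)
            - y
        )

    kg = _rate_guess(trace)
    start_pairs = [(4.0, 0.25), (10.0, 0.1), (2.0, 0.5)]
    best = None
    diagnostics = {}
    for hi, lo in start_pairs:
        p0 = [
            np.clip(np.log(kg * hi), *_LOG_BOUNDS),
            np.clip(np.log(kg * lo), *_LOG_BOUNDS),
            0.5 * amp0, 0.5 * amp0, y[-1],
        ]
        sol = least_squares(
            residuals, p0,
            bounds=([_LOG_BOUNDS[0]] * 2 + [-np.inf] * 3,
                    [_LOG_BOUNDS[1]] * 2 + [np.inf] * 3),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
        )
        if not sol.success:
            diagnostics[f"start_{hi}x_{lo}x"] = sol.message
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError("double-exponential fit did not converge", diagnostics)

    rss, sol = best
    lnk1, lnk2, a1, a2, y_inf = sol.x
    k1, k2 = float(np.exp(lnk1)), float(np.exp(lnk2))
    # sort fast-first, amplitudes travel with their rates
    (k1, a1), (k2, a2) = sorted(
        [(k1, float(a1)), (k2, float(a2))], key=lambda r: -r[0]
    )
    if k2 > 0 and k1 / k2 < 1.05:
        single = fit_single_exponential(trace)
        single.warnings.append("rate_collapse")
        return single

    se = _exp_se(sol, ["ln_k_a", "ln_k_b", "a_a", "a_b", "y_inf"])
    # map SEs onto the sorted ordering
    order = [0, 1] if np.exp(sol.x[0]) >= np.exp(sol.x[1]) else [1, 0]
    lnk_se = [se.get("ln_k_a", float("nan")), se.get("ln_k_b", float("nan"))]
    amp_se = [se.get("a_a", float("nan")), se.get("a_b", float("nan"))]
    se_out = {
        "k_u1": k1 * lnk_se[order[0]],
        "k_u2": k2 * lnk_se[order[1]],
        "a1": amp_se[order[0]],
        "a2": amp_se[order[1]],
        "y_inf": se.get("y_inf", float("nan")),
    }
    return ExpFitResult(
        model="double", k_u1=k1, k_u2=k2, a1=a1, a2=a2, y_inf=float(y_inf),
        se=se_out, rss=rss, n_points=len(y), aicc=_aicc(rss, len(y), 5),
        warnings=_boundary_warnings([k1, k2]),
    )


def _exp_se(sol, names):
    n, p = sol.jac.shape
    dof = max(n - p, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        diag = np.clip(np.diag(cov), 0.0, np.inf)
        return {name: float(np.sqrt(d)) for name, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {name: float("nan") for name in names}


#: AICc margin, rate-separation and amplitude-share guards for "double".
SELECT_AICC_MARGIN = 2.0
SELECT_RATE_RATIO = 3.0
SELECT_MIN_AMP_SHARE = 0.05


def select_model(trace: KineticTrace, override: str | None = None) -> ExpFitResult:
    """Fit both exponential models and pick one.

    Returns the double fit iff AICc(double) <= AICc(single) - 2 AND the rates
    are separated by >= 3x AND each phase carries >= 5% of the total
    amplitude AND the amplitudes share a sign (a monotone decay cannot have
    opposing phases; a mixed-sign "second phase" is noise chasing); otherwise
    the single fit. ``override`` in {'single','double'} forces the model
    regardless.
    """
    if override == "single":
        return fit_single_exponential(trace)
    if override == "double":
        return fit_double_exponential(trace)
    if override is not None:
        raise ValueError(f"override must be 'single' or 'double', got {override!r}")

    single_exc = double_exc = None
    single = double = None
    try:
        single = fit_single_exponential(trace)
    except FitError as exc:
        single_exc = exc
    try:
        double = fit_double_exponential(trace)
    except (FitError, TraceDataError) as exc:
        # a trace too short for the 5-parameter model can still be fit single
        double_exc = exc

    if single is None and double is None:
        raise FitError(
            "both exponential fits failed",
            {"single": str(single_exc), "double": str(double_exc)},
        )
    if double is None or double.model == "single":
        return double if double is not None else single
    if single is None:
        return double

    total_amp = abs(double.a1) + abs(double.a2)
    accept = (
        double.aicc <= single.aicc - SELECT_AICC_MARGIN
        and double.k_u1 / double.k_u2 >= SELECT_RATE_RATIO
        and total_amp > 0
        and min(abs(double.a1), abs(double.a2)) >= SELECT_MIN_AMP_SHARE * total_amp
        and double.a1 * double.a2 > 0
    )
    return double if accept else single


def build_rate_table(results) -> pd.DataFrame:
    """Assemble fitted rates into a tidy table, one row per condition.

    ``results`` is an iterable of ``(Condition, ExpFitResult)`` pairs; each
    (variant, detergent, temperature) condition may appear once. Missing slow
    rates are left as NA. Sorted by variant, detergent, temperature.
    """
    rows = []
    seen = set()
    for condition, fit in results:
        if not isinstance(condition, Condition):
            raise TypeError("expected (Condition, ExpFitResult) pairs")
        key = (condition.variant, condition.detergent_mM, condition.temperature_C)
        if key in seen:
            raise TraceDataError(f"duplicate condition {key}")
        seen.add(key)
        rows.append(
            {
                "variant": condition.variant,
                "ldao_mM": condition.detergent_mM,
                "lpr": condition.lpr,
                "temp_C": condition.temperature_C,
                "model": fit.model,
                "ku1_per_min": fit.k_u1,
                "ku1_se": fit.se.get("k_u1", float("nan")),
                "ku2_per_min": fit.k_u2 if fit.model == "double" else None,
                "ku2_se": fit.se.get("k_u2") if fit.model == "double" else None,
            }
        )
    columns = [
        "variant", "ldao_mM", "lpr", "temp_C", "model",
        "ku1_per_min", "ku1_se", "ku2_per_min", "ku2_se",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(
            ["variant", "ldao_mM", "temp_C"], kind="mergesort"
        ).reset_index(drop=True)
    return table


#: Median-filter window (samples) for extremum detection.
FILTER_WINDOW = 5


@dataclass
class AggregationSignature:
    """Rise-then-fall summary of a light-scattering (PMT voltage) trace."""

    t_peak_s: float | None
    rise_slope: float | None
    settle_rate_per_min: float | None
    no_peak: bool = False


@dataclass
class AnisotropySignature:
    """Drop-then-rise summary of a fluorescence-anisotropy trace."""

    r_initial: float
    r_min: float
    t_min_s: float
    r_final: float


def detect_aggregation_peak(trace: KineticTrace) -> AggregationSignature:
    """Locate the scattering maximum and the post-peak settling rate.

    The peak is taken on a 5-point median-filtered copy of the signal (robust
    to single-sample spikes). A peak at the final sample — or a signal that
    never falls materially after its maximum — yields a ``no_peak`` flag
    rather than an error. The settling rate comes from a single-exponential
    fit to the post-peak decay when enough points follow the peak.
    """
    _require_trace(trace, 20, kinds=("pmt_voltage",))
    filtered = medfilt(trace.signal, FILTER_WINDOW)
    span = float(np.ptp(filtered))
    if span == 0.0:
        return AggregationSignature(None, None, None, no_peak=True)
    i_peak = int(np.argmax(filtered))
    tail_drop = filtered[i_peak] - filtered[i_peak:].min()
    if i_peak >= len(trace) - 2 or tail_drop < 0.02 * span:
        return AggregationSignature(None, None, None, no_peak=True)

    t_peak = float(trace.time_s[i_peak])
    rise = np.polyfit(
        trace.time_s[: i_peak + 1], trace.signal[: i_peak + 1], 1
    )[0] if i_peak >= 1 else None

    settle = None
    if len(trace) - i_peak >= 10:
        tail = KineticTrace(
            time_s=trace.time_s[i_peak:],
            signal=trace.signal[i_peak:],
            signal_kind="ME215",  # reuse the decay fitter on the tail
            condition=trace.condition,
        )
        try:
            settle = fit_single_exponential(tail).k_u1
        except FitError:
            settle = None
    return AggregationSignature(
        t_peak_s=t_peak,
        rise_slope=float(rise) if rise is not None else None,
        settle_rate_per_min=settle,
        no_peak=False,
    )


def characterize_anisotropy(trace: KineticTrace) -> AnisotropySignature:
    """Summarize an anisotropy trace: initial level, filtered minimum, final level."""
    _require_trace(trace, 20, kinds=("anisotropy",))
    lo, hi = ANISOTROPY_RANGE
    if trace.signal.min() < lo or trace.signal.max() > hi:
        raise TraceDataError(f"anisotropy outside [{lo}, {hi}]")
    filtered = medfilt(trace.signal, FILTER_WINDOW)
    i_min = int(np.argmin(filtered))
    return AnisotropySignature(
        r_initial=float(np.median(trace.signal[:5])),
        r_min=float(filtered[i_min]),
        t_min_s=float(trace.time_s[i_min]),
        r_final=float(np.median(trace.signal[-5:])),
    )
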