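"""Temperature-ramp (T-scan) analysis: fraction unfolded and two-state melts.

The melt model is the standard van't Hoff sigmoid with linear pre- and
post-transition baselines and ΔCp fixed at zero::

    K(T)  = exp[(ΔH_vH / R) (1/Tm - 1/T)]        (T, Tm in kelvin)
    fu(T) = K / (1 + K)
    y(T)  = (yn0 + yn1 T)(1 - fu) + (yu0 + yu1 T) fu

Because thermal unfolding of the system this package targets is irreversible,
the fitted midpoint is an *apparent* Tm and is reported together with the
ramp rate of the scan that produced it.

The Tm-versus-detergent trend is summarized with a saturating-exponential
form ``Tm(c) = tm_max - delta * exp(-c / c0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL, celsius_to_kelvin
from .errors import FitError, TraceDataError
from .traces import ThermalScan


def fraction_unfolded(y0, yn, yu):
    """Fraction unfolded ``(y0 - yn) / (yu - yn)``.

    ``y0`` is the observed ellipticity, ``yn``/``yu`` the native and unfolded
    baselines; all three may be arrays (temperature-dependent baselines).
    """
    y0 = np.asarray(y0, dtype=float)
    yn = np.asarray(yn, dtype=float)
    yu = np.asarray(yu, dtype=float)
    if np.any(yn == yu):
        raise TraceDataError("degenerate baselines: yn == yu")
    return (y0 - yn) / (yu - yn)


@dataclass
class TwoStateFit:
    """Result of a two-state melt fit.

    ``tm_C`` is the apparent transition midpoint, ``dh_vh_kcal_mol`` the
    apparent van't Hoff enthalpy (the steepness parameter), the baselines are
    (intercept, slope-per-°C) pairs. ``se`` maps parameter names to standard
    errors where the covariance was estimable.
    """

    tm_C: float
    dh_vh_kcal_mol: float
    native_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    fitted_curve: np.ndarray
    rss: float
    se: dict
    ramp_C_per_min: float
    warnings: list = field(default_factory=list)

    def fraction_unfolded_at(self, temp_C):
        """Model fraction unfolded at the given temperature(s)."""
        return _fu(np.asarray(temp_C, dtype=float), self.tm_C, self.dh_vh_kcal_mol)


def _fu(temp_C, tm_C, dh):
    t_k = celsius_to_kelvin(temp_C)
    tm_k = celsius_to_kelvin(tm_C)
    lnk = (dh / R_KCAL) * (1.0 / tm_k - 1.0 / t_k)
    # logistic in ln K, stable for large |ln K|
    return 1.0 / (1.0 + np.exp(-lnk))


def _two_state_signal(temp_C, tm_C, dh, yn0, yn1, yu0, yu1):
    fu = _fu(temp_C, tm_C, dh)
    return (yn0 + yn1 * temp_C) * (1.0 - fu) + (yu0 + yu1 * temp_C) * fu


def _robust_line(x, y):
    if x.size < 2 or np.ptp(x) == 0:
        return float(np.median(y)), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def _initial_tm(temp, signal):
    """Midpoint guess: temperature of steepest change of the smoothed signal."""
    if signal.size >= 5:
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(signal, kernel, mode="same")
    else:
        smooth = signal
    deriv = np.gradient(smooth, temp)
    i = int(np.argmax(np.abs(deriv)))
    return float(temp[i])


def fit_two_state(scan: ThermalScan, baseline_mode: str = "fit") -> TwoStateFit:
    """Fit the two-state melt model to a thermal scan.

    ``baseline_mode='fit'`` refines linear native/unfolded baselines together
    with (Tm, ΔH_vH); ``'fixed'`` freezes the baselines at robust line fits to
    the outer 20% of points on each side. Initialization is multi-start over
    ΔH_vH ∈ {20, 50, 100} kcal/mol, with Tm seeded from the steepest point of
    the smoothed signal; the lowest-RSS solution wins, ties broken by the
    smaller |ΔH_vH|.
    """
    if baseline_mode not in ("fit", "fixed"):
        raise ValueError("baseline_mode must be 'fit' or 'fixed'")
    temp = scan.temperature_C
    sig = scan.signal
    if len(scan) < 10:
        raise TraceDataError("two-state fit requires at least 10 points")

    n_edge = max(2, int(0.2 * temp.size))
    yn0, yn1 = _robust_line(temp[:n_edge], sig[:n_edge])
    yu0, yu1 = _robust_line(temp[-n_edge:], sig[-n_edge:])
    tm0 = _initial_tm(temp, sig)
    tm_lo, tm_hi = float(temp[0]), float(temp[-1])
    tm0 = min(max(tm0, tm_lo + 1e-6), tm_hi - 1e-6)

    if baseline_mode == "fit":
        def residuals(p):
            return _two_state_signal(temp, *p) - sig

        def pack(dh):
            return np.array([tm0, dh, yn0, yn1, yu0, yu1])

        lower = [tm_lo, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        upper = [tm_hi, 1e4, np.inf, np.inf, np.inf, np.inf]
        names = ["tm_C", "dh_vh_kcal_mol", "yn0", "yn1", "yu0", "yu1"]
    else:
        def residuals(p):
            return _two_state_signal(temp, p[0], p[1], yn0, yn1, yu0, yu1) - sig

        def pack(dh):
            return np.array([tm0, dh])

        lower = [tm_lo, 1e-3]
        upper = [tm_hi, 1e4]
        names = ["tm_C", "dh_vh_kcal_mol"]

    best = None
    diagnostics = {}
    for dh_start in (20.0, 50.0, 100.0):
        try:
            sol = least_squares(
                residuals, pack(dh_start), bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception as exc:
            diagnostics[f"start_dh_{dh_start}"] = str(exc)
            continue
        if not sol.success:
            diagnostics[f"start_dh_{dh_start}"] = sol.message
            continue
        rss = float(np.sum(sol.fun**2))
        if (
            best is None
            or rss < best[0] - 1e-12 * max(1.0, best[0])
            or (abs(rss - best[0]) <= 1e-12 * max(1.0, best[0])
                and abs(sol.x[1]) < abs(best[1].x[1]))
        ):
            best = (rss, sol)
    if best is None:
        raise FitError("two-state melt fit did not converge", diagnostics)

    rss, sol = best
    p = sol.x
    se = _se_from_jacobian(sol.jac, sol.fun, names)
    tm_c, dh = float(p[0]), float(p[1])
    if baseline_mode == "fit":
        yn0, yn1, yu0, yu1 = (float(v) for v in p[2:])

    warnings = []
    span = tm_hi - tm_lo
    if tm_c - tm_lo < 0.02 * span or tm_hi - tm_c < 0.02 * span:
        warnings.append("tm_at_scan_boundary")
    # baselines crossing near the midpoint make fu ill-defined there
    t_near = np.linspace(tm_c - 5.0, tm_c + 5.0, 21)
    if np.any(np.abs((yn0 + yn1 * t_near) - (yu0 + yu1 * t_near)) < 1e-12):
        warnings.append("baselines_cross_near_tm")

    return TwoStateFit(
        tm_C=tm_c,
        dh_vh_kcal_mol=dh,
        native_baseline=(yn0, yn1),
        unfolded_baseline=(yu0, yu1),
        fitted_curve=_two_state_signal(temp, tm_c, dh, yn0, yn1, yu0, yu1),
        rss=rss,
        se=se,
        ramp_C_per_min=scan.ramp_C_per_min,
        warnings=warnings,
    )


def _se_from_jacobian(jac, residual, names):
    """Standard errors from the Gauss-Newton covariance; NaN if singular."""
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(np.sum(residual**2)) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        diag = np.clip(np.diag(cov), 0.0, np.inf)
        return {name: float(np.sqrt(d)) for name, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {name: float("nan") for name in names}


@dataclass
class SaturationFit:
    """Saturating-exponential summary of Tm versus detergent concentration."""

    tm_max_C: float
    delta_C: float
    c0_mM: float
    rss: float

    def predict(self, conc_mM):
        return self.tm_max_C - self.delta_C * np.exp(
            -np.asarray(conc_mM, dtype=float) / self.c0_mM
        )


def fit_tm_saturation(points) -> SaturationFit:
    """Fit ``Tm(c) = tm_max - delta * exp(-c/c0)`` to (conc_mM, tm_C) pairs.

    Requires at least four points with distinct concentrations. The predicted
    Tm is non-decreasing in concentration by construction (delta >= 0, c0 > 0).
    """
    pts = sorted((float(c), float(tm)) for c, tm in points)
    conc = np.array([c for c, _ in pts])
    tm = np.array([t for _, t in pts])
    if conc.size < 4:
        raise TraceDataError("saturation fit requires >= 4 points")
    if np.unique(conc).size != conc.size:
        raise TraceDataError("saturation fit requires distinct concentrations")

    tm_max0 = float(tm.max())
    delta0 = max(float(tm.max() - tm.min()), 1e-6)

    def residuals(p):
        tm_max, delta, c0 = p
        return tm_max - delta * np.exp(-conc / c0) - tm

    best = None
    for c0_start in (conc.min(), float(np.median(conc)), conc.max()):
        sol = least_squares(
            residuals,
            [tm_max0, delta0, max(c0_start, 1e-3)],
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
        )
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitError("saturation fit did not converge")
    rss, (tm_max, delta, c0) = best
    return SaturationFit(
        tm_max_C=float(tm_max), delta_C=float(delta), c0_mM=float(c0), rss=rss
    )
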