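"""Arrhenius regression of unfolding rates and linearity diagnostics.

The activation energy comes from an unweighted least-squares fit of ln k
against 1/T (kelvin): slope = -Eact/R with R = 1.987 cal K^-1 mol^-1. Rate
standard errors, where available, are carried into the report but never used
as weights, matching the conventional (unweighted) published procedure.

Whether a rate set is "Arrhenius-linear" is decided by comparing linear and
quadratic models in 1/T on corrected Akaike information: the set is linear
unless the quadratic model improves AICc by more than 2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import R_KCAL, celsius_to_kelvin
from .errors import TraceDataError


@dataclass
class ArrheniusFit:
    """Arrhenius regression result.

    ``slope_K`` (kelvin) and ``eact_kcal_mol`` satisfy slope = -Eact/R
    identically. ``r_squared`` is defined only for >= 3 points, ``se_eact``
    only when the regression has residual degrees of freedom.
    """

    eact_kcal_mol: float
    ln_a: float
    slope_K: float
    r_squared: float | None
    se_eact_kcal_mol: float | None
    points: list
    linear: bool | None = None

    def predict_rate(self, temp_C):
        """Rate (min^-1) on the fitted line at the given temperature(s)."""
        inv_t = 1.0 / celsius_to_kelvin(np.asarray(temp_C, dtype=float))
        return np.exp(self.ln_a + self.slope_K * inv_t)


def arrhenius_fit(points) -> ArrheniusFit:
    """Unweighted least squares of ln k vs 1/T over (temp_C, rate_per_min) pairs.

    Requires >= 2 points with distinct temperatures and positive rates.
    Points are sorted by temperature internally so the result is independent
    of input order.
    """
    pts = sorted((float(t), float(k)) for t, k in points)
    if len(pts) < 2:
        raise TraceDataError("Arrhenius fit requires >= 2 points")
    temps = np.array([t for t, _ in pts])
    rates = np.array([k for _, k in pts])
    if np.any(rates <= 0):
        raise ValueError("all rates must be positive")
    if np.unique(temps).size != temps.size:
        raise TraceDataError("duplicate temperatures in Arrhenius input")

    x = 1.0 / celsius_to_kelvin(temps)
    y = np.log(rates)

    if len(pts) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r_squared = None
        se_eact = None
    else:
        reg = stats.linregress(x, y)
        slope, intercept = float(reg.slope), float(reg.intercept)
        r_squared = float(reg.rvalue**2)
        se_eact = float(reg.stderr * R_KCAL) if len(pts) > 2 else None

    return ArrheniusFit(
        eact_kcal_mol=float(-slope * R_KCAL),
        ln_a=float(intercept),
        slope_K=float(slope),
        r_squared=r_squared,
        se_eact_kcal_mol=se_eact,
        points=pts,
    )


@dataclass
class LinearityResult:
    """Outcome of the linear-vs-quadratic Arrhenius diagnostic.

    ``linear`` is None when fewer than four points are available (the
    comparison is then undefined). ``curvature`` is the quadratic coefficient
    in 1/T with its standard error; ``delta_aicc`` is
    AICc(quadratic) - AICc(linear).
    """

    linear: bool | None
    curvature: float | None = None
    curvature_se: float | None = None
    delta_aicc: float | None = None


#: AICc improvement the quadratic model must exceed to reject linearity.
LINEARITY_AICC_MARGIN = 2.0


def _aicc(rss, n, p):
    if n - p - 1 <= 0:
        return float("inf")
    return n * np.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def linearity_check(points) -> LinearityResult:
    """Decide whether (temp_C, rate) points follow a single Arrhenius line.

    Accepts the same input as :func:`arrhenius_fit` or an
    :class:`ArrheniusFit` (its stored points are used). With fewer than four
    points the result carries ``linear=None``.
    """
    if isinstance(points, ArrheniusFit):
        points = points.points
    pts = sorted((float(t), float(k)) for t, k in points)
    if len(pts) < 4:
        return LinearityResult(linear=None)
    temps = np.array([t for t, _ in pts])
    rates = np.array([k for _, k in pts])
    if np.any(rates <= 0):
        raise ValueError("all rates must be positive")

    x = 1.0 / celsius_to_kelvin(temps)
    y = np.log(rates)
    # center x for conditioning; curvature coefficient is unaffected
    xc = x - x.mean()
    n = len(pts)

    design_l = np.column_stack([np.ones(n), xc])
    lin_coef, *_ = np.linalg.lstsq(design_l, y, rcond=None)
    rss_lin = float(np.sum((design_l @ lin_coef - y) ** 2))

    # data already linear to numerical precision: the quadratic comparison
    # would only be ranking rounding noise
    if rss_lin <= n * (1e-10 * max(1.0, float(np.max(np.abs(y))))) ** 2:
        return LinearityResult(
            linear=True, curvature=0.0, curvature_se=float("nan"), delta_aicc=None
        )

    design_q = np.column_stack([np.ones(n), xc, xc**2])
    quad_coef, *_ = np.linalg.lstsq(design_q, y, rcond=None)
    resid_q = design_q @ quad_coef - y
    rss_quad = float(np.sum(resid_q**2))

    dof = n - 3
    if dof > 0:
        s2 = rss_quad / dof
        cov = np.linalg.inv(design_q.T @ design_q) * s2
        curv_se = float(np.sqrt(max(cov[2, 2], 0.0)))
    else:
        curv_se = float("nan")

    delta = _aicc(rss_quad, n, 3) - _aicc(rss_lin, n, 2)
    return LinearityResult(
        linear=bool(delta > -LINEARITY_AICC_MARGIN),
        curvature=float(quad_coef[2]),
        curvature_se=curv_se,
        delta_aicc=float(delta),
    )
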