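"""Trace containers, delimited-text I/O, unit conversions and preprocessing.

Two containers cover every experiment in the study design:

* :class:`KineticTrace` — an isothermal time series of a spectroscopic
  observable (mean residue ellipticity at 215 nm, fluorescence anisotropy, or
  photomultiplier voltage as a light-scattering proxy).
* :class:`ThermalScan` — a continuous temperature-ramp series of ellipticity.

The on-disk format is a UTF-8 CSV with ``# key=value`` metadata header lines
followed by a column header (``time_s,signal[,pmt_v][,anisotropy]`` or
``temp_C,signal``). Times are stored in seconds, temperatures in degrees
Celsius; rate constants are reported in min^-1 only at fit time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TraceDataError, TraceFormatError

#: Allowed signal kinds for a kinetic trace.
SIGNAL_KINDS = ("ME215", "fraction_unfolded", "anisotropy", "pmt_voltage")

#: Physically plausible range for steady-state fluorescence anisotropy.
ANISOTROPY_RANGE = (-0.2, 0.4)

#: Minimum number of samples any fit will accept.
MIN_SAMPLES = 10

#: Default instrument dead time, seconds.
DEFAULT_DEAD_TIME_S = 30.0


def lpr(detergent_mM: float, protein_uM: float) -> float:
    """Detergent-to-protein molar ratio from mM detergent and µM protein.

    Both concentrations must be positive; the mM/µM unit mismatch contributes
    the factor of 1000.
    """
    if detergent_mM <= 0 or protein_uM <= 0:
        raise ValueError(
            f"concentrations must be positive, got detergent={detergent_mM} mM, "
            f"protein={protein_uM} uM"
        )
    return detergent_mM * 1000.0 / protein_uM


def mdeg_to_molar_ellipticity(
    theta_mdeg, mrw: float, conc_mg_ml: float, pathlength_cm: float
):
    """Convert raw CD signal (millidegrees) to mean residue ellipticity.

    [theta] = theta_mdeg * MRW / (10 * l * c) with the mean residue weight
    ``mrw`` in g/mol, concentration in mg/mL and pathlength in cm; the result
    is in deg cm^2 dmol^-1. Linear in ``theta_mdeg`` (any sign).
    """
    if mrw <= 0 or conc_mg_ml <= 0 or pathlength_cm <= 0:
        raise ValueError("mrw, concentration and pathlength must be positive")
    return np.asarray(theta_mdeg, dtype=float) * mrw / (
        10.0 * pathlength_cm * conc_mg_ml
    )


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata attached to every trace.

    ``variant`` is the protein construct label (``WT`` or the Cys-less ``C0``);
    ``detergent_mM`` is the LDAO concentration, ``protein_uM`` the protein
    concentration. ``temperature_C`` is set for isothermal experiments only.
    """

    variant: str
    detergent_mM: float
    protein_uM: float
    temperature_C: float | None = None

    def __post_init__(self):
        if self.detergent_mM <= 0:
            raise ValueError(f"detergent_mM must be > 0, got {self.detergent_mM}")
        if self.protein_uM <= 0:
            raise ValueError(f"protein_uM must be > 0, got {self.protein_uM}")

    @property
    def lpr(self) -> float:
        """Detergent:protein molar ratio (dimensionless)."""
        return lpr(self.detergent_mM, self.protein_uM)


def _check_strictly_increasing(x: np.ndarray, name: str):
    bad = np.nonzero(np.diff(x) <= 0)[0]
    if bad.size:
        raise TraceDataError(
            f"{name} must be strictly increasing; violation at row {bad[0] + 1} "
            f"({name}[{bad[0]}]={x[bad[0]]!r} >= {name}[{bad[0] + 1}]={x[bad[0] + 1]!r})"
        )


@dataclass
class KineticTrace:
    """One isothermal time series of a spectroscopic observable.

    ``time_s`` is seconds from the start of acquisition (strictly increasing);
    ``signal`` holds the observable named by ``signal_kind``. ``extra`` carries
    any companion channels recorded alongside the primary one (``pmt_v``,
    ``anisotropy``, simulator species fractions, ...). ``flags`` accumulates
    non-fatal data warnings.
    """

    time_s: np.ndarray
    signal: np.ndarray
    signal_kind: str
    condition: Condition
    dead_time_s: float = 0.0
    extra: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(
                f"signal_kind must be one of {SIGNAL_KINDS}, got {self.signal_kind!r}"
            )
        if self.time_s.shape != self.signal.shape:
            raise TraceDataError("time and signal must have equal length")
        _check_strictly_increasing(self.time_s, "time_s")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")
        if self.signal_kind == "anisotropy":
            lo, hi = ANISOTROPY_RANGE
            if self.signal.size and (
                self.signal.min() < lo or self.signal.max() > hi
            ):
                raise TraceDataError(
                    f"anisotropy values outside [{lo}, {hi}]"
                )

    def __len__(self):
        return self.time_s.size

    @property
    def time_min(self) -> np.ndarray:
        """Time axis in minutes (rates are reported in min^-1)."""
        return self.time_s / 60.0


@dataclass
class ThermalScan:
    """One temperature-ramp series of ellipticity (a T-scan)."""

    temperature_C: np.ndarray
    signal: np.ndarray
    ramp_C_per_min: float
    condition: Condition
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_C.shape != self.signal.shape:
            raise TraceDataError("temperature and signal must have equal length")
        _check_strictly_increasing(self.temperature_C, "temp_C")
        if self.ramp_C_per_min <= 0:
            raise ValueError("ramp_C_per_min must be > 0")

    def __len__(self):
        return self.temperature_C.size


def trim_dead_time(
    trace: KineticTrace, dead_time_s: float = DEFAULT_DEAD_TIME_S
) -> KineticTrace:
    """Drop samples acquired before ``dead_time_s``.

    Absolute times are kept (no re-zeroing), so the fitted decay is evaluated
    on the true clock and the unobserved burst phase is never extrapolated.
    """
    if dead_time_s < 0:
        raise ValueError("dead_time_s must be >= 0")
    keep = trace.time_s >= dead_time_s
    n_keep = int(keep.sum())
    if n_keep < MIN_SAMPLES:
        raise TraceDataError(
            f"trimming {dead_time_s} s leaves {n_keep} samples (< {MIN_SAMPLES})"
        )
    extra = {k: np.asarray(v)[keep] for k, v in trace.extra.items()}
    return replace(
        trace,
        time_s=trace.time_s[keep],
        signal=trace.signal[keep],
        dead_time_s=dead_time_s,
        extra=extra,
        flags=list(trace.flags),
    )


def normalize_to_fraction(
    trace: KineticTrace, y_start: float, y_end: float
) -> KineticTrace:
    """Affinely map the signal so ``y_start`` -> 0 and ``y_end`` -> 1.

    Values outside [-0.05, 1.05] are flagged (``out_of_range_fraction``), not
    clamped, so downstream fit residuals stay unbiased.
    """
    if y_start == y_end:
        raise TraceDataError("degenerate normalization: y_start == y_end")
    frac = (trace.signal - y_start) / (y_end - y_start)
    flags = list(trace.flags)
    n_out = int(np.sum((frac < -0.05) | (frac > 1.05)))
    if n_out:
        flags.append(f"out_of_range_fraction:{n_out}")
    return replace(
        trace,
        signal=frac,
        signal_kind="fraction_unfolded",
        extra=dict(trace.extra),
        flags=flags,
    )


# --- delimited-text dialect -------------------------------------------------

_META_KEYS = {
    "variant": str,
    "ldao_mM": float,
    "protein_uM": float,
    "temp_C": float,
    "ramp_C_per_min": float,
    "dead_time_s": float,
    "signal_kind": str,
}


def _parse_header(path) -> tuple[dict, str]:
    meta: dict = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                entry = stripped.lstrip("#").strip()
                if "=" not in entry:
                    raise TraceFormatError(
                        f"malformed metadata line {stripped!r} in {path}"
                    )
                key, _, value = entry.partition("=")
                key = key.strip()
                caster = _META_KEYS.get(key, str)
                meta[key] = caster(value.strip())
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _condition_from_meta(meta: dict, path) -> Condition:
    try:
        return Condition(
            variant=meta.get("variant", "WT"),
            detergent_mM=meta["ldao_mM"],
            protein_uM=meta["protein_uM"],
            temperature_C=meta.get("temp_C"),
        )
    except KeyError as exc:
        raise TraceFormatError(f"missing metadata key {exc} in {path}") from exc


def read_trace(path, kind: str = "kinetic") -> KineticTrace | ThermalScan:
    """Read a trace CSV in the package dialect.

    ``kind`` selects the container: ``kinetic`` expects a ``time_s`` column,
    ``thermal`` expects ``temp_C``. Missing mandatory columns raise
    :class:`TraceFormatError`; ordering violations and short files raise
    :class:`TraceDataError`.
    """
    if kind not in ("kinetic", "thermal"):
        raise ValueError(f"kind must be 'kinetic' or 'thermal', got {kind!r}")
    meta, body = _parse_header(path)
    try:
        df = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceFormatError(f"cannot parse CSV body of {path}: {exc}") from exc
    abscissa = "time_s" if kind == "kinetic" else "temp_C"
    for col in (abscissa, "signal"):
        if col not in df.columns:
            raise TraceFormatError(f"missing mandatory column {col!r} in {path}")
    if len(df) < MIN_SAMPLES:
        raise TraceDataError(
            f"{path} has {len(df)} rows; at least {MIN_SAMPLES} required"
        )
    condition = _condition_from_meta(meta, path)
    if kind == "thermal":
        return ThermalScan(
            temperature_C=df["temp_C"].to_numpy(),
            signal=df["signal"].to_numpy(),
            ramp_C_per_min=meta.get("ramp_C_per_min", 1.0),
            condition=condition,
        )
    extra = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in (abscissa, "signal")
    }
    return KineticTrace(
        time_s=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        signal_kind=meta.get("signal_kind", "ME215"),
        condition=condition,
        dead_time_s=meta.get("dead_time_s", 0.0),
        extra=extra,
    )


def write_trace(trace: KineticTrace | ThermalScan, path) -> None:
    """Write a trace in the package CSV dialect (inverse of :func:`read_trace`)."""
    cond = trace.condition
    meta = {
        "variant": cond.variant,
        "ldao_mM": cond.detergent_mM,
        "protein_uM": cond.protein_uM,
    }
    if isinstance(trace, ThermalScan):
        meta["ramp_C_per_min"] = trace.ramp_C_per_min
        columns = {"temp_C": trace.temperature_C, "signal": trace.signal}
    else:
        if cond.temperature_C is not None:
            meta["temp_C"] = cond.temperature_C
        meta["dead_time_s"] = trace.dead_time_s
        meta["signal_kind"] = trace.signal_kind
        columns = {"time_s": trace.time_s, "signal": trace.signal}
        for name, values in trace.extra.items():
            arr = np.asarray(values)
            if arr.shape == trace.time_s.shape and arr.dtype.kind in "fiu":
                columns[name] = arr
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        pd.DataFrame(columns).to_csv(fh, index=False, float_format="%.10g")
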