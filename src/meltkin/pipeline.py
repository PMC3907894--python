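"""End-to-end orchestration: trace directory in, report tables out.

A run reads every trace CSV under the input path, fits isothermal traces with
the exponential model policy, fits T-scans two-state, groups rates for
Arrhenius regression (activation energy is derived only for groups that pass
the linearity diagnostic, unless overridden), and assembles a report that
mirrors the study's published summaries: a rate table, an apparent-Tm table
and an activation-energy table. Per-trace warnings are accumulated, never
dropped; the run fails only if every trace fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrhenius import arrhenius_fit, linearity_check
from .errors import ConfigError, MeltkinError, TraceDataError
from .kinetics import build_rate_table, select_model
from .melt import fit_two_state
from .traces import read_trace, trim_dead_time

MIN_ARRHENIUS_POINTS = 4


@dataclass
class AnalysisConfig:
    """One fully-determined analysis run."""

    input_dir: str
    dead_time_s: float = 30.0
    model_policy: str = "auto"  # auto | single | double
    linearity_override: bool = False
    baseline_mode: str = "fit"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.model_policy not in ("auto", "single", "double"):
            raise ConfigError(f"invalid model policy {self.model_policy!r}")
        if self.dead_time_s < 0:
            raise ConfigError("dead_time_s must be >= 0")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Analysis outputs plus provenance."""

    rate_table: pd.DataFrame
    tm_table: pd.DataFrame
    eact_table: pd.DataFrame
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def df_records(df):
            return json.loads(df.to_json(orient="records"))

        return {
            "rate_table": df_records(self.rate_table),
            "tm_table": df_records(self.tm_table),
            "eact_table": df_records(self.eact_table),
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


def _classify(path: Path) -> str | None:
    """Peek at the column header to decide kinetic vs thermal."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    cols = [c.strip() for c in line.split(",")]
                    if "time_s" in cols:
                        return "kinetic"
                    if "temp_C" in cols:
                        return "thermal"
                    return None
    except OSError:
        return None
    return None


def run_analysis(config: AnalysisConfig) -> Report:
    """Execute a full analysis run; deterministic given inputs and config."""
    root = Path(config.input_dir)
    if not root.exists():
        raise ConfigError(f"input path {root} does not exist")
    paths = sorted(root.glob("*.csv")) if root.is_dir() else [root]
    if not paths:
        raise TraceDataError(f"no traces found under {root}")

    warnings: list = []
    kinetic_results = []
    tm_rows = []
    n_failed = 0
    override = None if config.model_policy == "auto" else config.model_policy

    for path in paths:
        kind = _classify(path)
        if kind is None:
            warnings.append(f"{path.name}: unrecognized columns, skipped")
            n_failed += 1
            continue
        try:
            trace = read_trace(path, kind=kind)
            if kind == "kinetic":
                dead = max(config.dead_time_s, trace.dead_time_s)
                if dead > trace.time_s[0]:
                    trace = trim_dead_time(trace, dead)
                fit = select_model(trace, override=override)
                for w in fit.warnings:
                    warnings.append(f"{path.name}: {w}")
                kinetic_results.append((trace.condition, fit))
            else:
                fit = fit_two_state(trace, baseline_mode=config.baseline_mode)
                for w in fit.warnings:
                    warnings.append(f"{path.name}: {w}")
                tm_rows.append(
                    {
                        "variant": trace.condition.variant,
                        "ldao_mM": trace.condition.detergent_mM,
                        "tm_C": fit.tm_C,
                        "tm_se": fit.se.get("tm_C", float("nan")),
                        "dh_vh_kcal_mol": fit.dh_vh_kcal_mol,
                        "ramp_C_per_min": fit.ramp_C_per_min,
                    }
                )
        except MeltkinError as exc:
            warnings.append(f"{path.name}: {type(exc).__name__}: {exc}")
            n_failed += 1

    if n_failed == len(paths):
        raise TraceDataError("every trace failed to parse or fit")

    rate_table = build_rate_table(kinetic_results)
    tm_table = pd.DataFrame(
        tm_rows,
        columns=["variant", "ldao_mM", "tm_C", "tm_se",
                 "dh_vh_kcal_mol", "ramp_C_per_min"],
    )
    if len(tm_table):
        tm_table = tm_table.sort_values(
            ["variant", "ldao_mM"], kind="mergesort"
        ).reset_index(drop=True)

    eact_rows = []
    if len(rate_table):
        for (variant, ldao), group in rate_table.groupby(["variant", "ldao_mM"]):
            pts = list(zip(group["temp_C"], group["ku1_per_min"]))
            if len(pts) < 2:
                continue
            lin = linearity_check(pts) if len(pts) >= MIN_ARRHENIUS_POINTS else None
            is_linear = lin.linear if lin is not None else None
            row = {
                "variant": variant, "ldao_mM": ldao,
                "n_points": len(pts), "linear": is_linear,
            }
            if is_linear or config.linearity_override:
                fit = arrhenius_fit(pts)
                row.update(
                    eact_kcal_mol=fit.eact_kcal_mol,
                    eact_se=fit.se_eact_kcal_mol,
                    ln_a=fit.ln_a,
                    r_squared=fit.r_squared,
                )
            else:
                warnings.append(
                    f"{variant}/{ldao:g} mM: Arrhenius plot non-linear or "
                    "under-determined; activation energy not derived"
                )
            eact_rows.append(row)
    eact_table = pd.DataFrame(
        eact_rows,
        columns=["variant", "ldao_mM", "n_points", "linear",
                 "eact_kcal_mol", "eact_se", "ln_a", "r_squared"],
    )

    report = Report(
        rate_table=rate_table,
        tm_table=tm_table,
        eact_table=eact_table,
        warnings=warnings,
        provenance={
            "package_version": __version__,
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
            "n_traces": len(paths),
            "n_failed": n_failed,
        },
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: Report, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
    report.rate_table.to_csv(out / "rate_table.csv", index=False)
    report.tm_table.to_csv(out / "tm_table.csv", index=False)
    report.eact_table.to_csv(out / "eact_table.csv", index=False)


def compare_variants(report: Report, ref: str = "WT", alt: str = "C0") -> pd.DataFrame:
    """Per-detergent differences (alt - ref) of apparent Tm and Eact.

    Standard errors are combined in quadrature. Raises if either variant is
    absent from the report.
    """
    for variant in (ref, alt):
        present = (
            variant in set(report.tm_table.get("variant", []))
            or variant in set(report.eact_table.get("variant", []))
        )
        if not present:
            raise TraceDataError(f"variant {variant!r} missing from report")

    rows = []
    tm = report.tm_table.set_index(["variant", "ldao_mM"]) if len(report.tm_table) else None
    ea = report.eact_table.set_index(["variant", "ldao_mM"]) if len(report.eact_table) else None
    ldao_values = sorted(
        set(report.tm_table.get("ldao_mM", [])) | set(report.eact_table.get("ldao_mM", []))
    )
    for ldao in ldao_values:
        row: dict = {"ldao_mM": ldao}
        if tm is not None and (ref, ldao) in tm.index and (alt, ldao) in tm.index:
            a, b = tm.loc[(alt, ldao)], tm.loc[(ref, ldao)]
            row["delta_tm_C"] = float(a["tm_C"] - b["tm_C"])
            row["delta_tm_se"] = float(
                np.sqrt(np.nan_to_num(a["tm_se"]) ** 2 + np.nan_to_num(b["tm_se"]) ** 2)
            )
        if ea is not None and (ref, ldao) in ea.index and (alt, ldao) in ea.index:
            a, b = ea.loc[(alt, ldao)], ea.loc[(ref, ldao)]
            if pd.notna(a.get("eact_kcal_mol")) and pd.notna(b.get("eact_kcal_mol")):
                row["delta_eact_kcal_mol"] = float(
                    a["eact_kcal_mol"] - b["eact_kcal_mol"]
                )
                se_a = a.get("eact_se") or 0.0
                se_b = b.get("eact_se") or 0.0
                row["delta_eact_se"] = float(np.sqrt(se_a**2 + se_b**2))
        if len(row) > 1:
            rows.append(row)
    return pd.DataFrame(rows)
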