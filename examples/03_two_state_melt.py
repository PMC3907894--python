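"""Fit a thermal melt two-state and summarize Tm versus detergent.

Generates a noiseless van't Hoff melt (midpoint 70 degC, apparent enthalpy
80 kcal/mol) on flat ellipticity baselines, refits it, then fits the
saturating-exponential trend of apparent Tm against detergent concentration.
"""

import numpy as np

import meltkin as mk
from meltkin.melt import _two_state_signal

temps = np.arange(4.0, 95.01, 0.5)
signal = _two_state_signal(temps, 70.0, 80.0, -9000.0, 0.0, -1000.0, 0.0)
scan = mk.ThermalScan(
    temperature_C=temps, signal=signal, ramp_C_per_min=1.0,
    condition=mk.Condition("WT", 13.0, 5.0),
)
fit = mk.fit_two_state(scan)
print(f"apparent Tm = {fit.tm_C:.2f} C  (ramp {fit.ramp_C_per_min:g} C/min)")
print(f"apparent dH_vH = {fit.dh_vh_kcal_mol:.1f} kcal/mol")
print("(the melt is irreversible, so Tm is kinetic-apparent, not equilibrium)")

# Tm vs detergent: rises steeply at low detergent, saturates by ~65 mM
points = [(c, 71.0 - 10.0 * np.exp(-c / 12.0))
          for c in (5.0, 13.0, 30.0, 65.0, 80.0, 100.0)]
sat = mk.fit_tm_saturation(points)
print(f"\nTm(c) = {sat.tm_max_C:.1f} - {sat.delta_C:.1f} * exp(-c / "
      f"{sat.c0_mM:.1f} mM)")
print(f"plateau Tm = {sat.tm_max_C:.1f} C; half-saturation scale = "
      f"{sat.c0_mM:.1f} mM detergent")
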