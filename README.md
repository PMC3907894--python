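# meltkin

Analysis of irreversible thermal denaturation of detergent-solubilized
membrane proteins, with a forward simulator for validation. The package was
built around the unfolding behaviour of the human mitochondrial channel
hVDAC-2, a 19-stranded transmembrane β-barrel refolded in LDAO micelles, but
every operation is generic: it applies to any protein whose thermal unfolding
is kinetically controlled rather than a reversible equilibrium.

It is a library first — import it from Python, or run the short narrative
scripts in `examples/` — with a thin `meltkin` command-line wrapper for
directory-scale runs.

## The science

At temperatures below the apparent melting midpoint, isothermal CD traces of
the barrel show **two sequential irreversible transitions**. The model is a
Lumry–Eyring variant in which *both* steps are irreversible:

```
N  --k1-->  N*  --k2-->  D
```

N is the native barrel, N\* a kinetically trapped intermediate that never
refolds (cooling and reheating shows no recovery of the fast phase), and D
the aggregated end state. Above the midpoint the familiar pseudo-two-state
N→D behaviour emerges automatically when k2 ≫ k1.

The analysis stages mirror standard practice in the field:

* **Fraction unfolded** — fu = (y₀ − y_n)/(y_u − y_n) from molar ellipticity
  at 215 nm, with mean residue ellipticity
  [θ] = θ_mdeg·MRW/(10·l·c).
* **Two-state melt fit** — van't Hoff sigmoid K(T) = exp[(ΔH_vH/R)(1/Tm − 1/T)],
  fu = K/(1+K), linear baselines, ΔCp = 0. Because the melts are
  irreversible, Tm is reported as *apparent* and annotated with the ramp rate.
* **Isothermal kinetics** — y(t) = y∞ + a₁e^(−k_u1 t) (+ a₂e^(−k_u2 t)),
  rates in min⁻¹, fast-first; model selection by AICc with rate-separation,
  amplitude-share and amplitude-sign guards, plus an explicit override.
* **Arrhenius analysis** — unweighted least squares of ln k on 1/T (kelvin);
  slope = −E_act/R with R = 1.987 cal K⁻¹ mol⁻¹; a linear-vs-quadratic AICc
  diagnostic decides whether an activation energy may be derived.
* **Forward simulator** — exact closed-form species fractions for the
  sequential scheme, Arrhenius-temperature-dependent rates, and three
  observables: CD ellipticity, tryptophan anisotropy (drop-then-rise), and a
  light-scattering (PMT) channel obeying dA_s/dt = k2·f_N\* − k_settle·A_s,
  which reproduces the rise-then-fall aggregation signature. Temperature
  ramps, piecewise heat–cool–reheat protocols and a full factorial study
  generator (two variants × six detergent concentrations × seven
  temperatures, with a ground-truth manifest) are included.

## Worked example

```python
import numpy as np, meltkin as mk

cond = mk.Condition(variant="WT", detergent_mM=5.0, protein_uM=5.0,
                    temperature_C=80.0)
t_s = np.arange(0.0, 300.5, 1.0)          # 5 min at 1 Hz
t = t_s / 60.0
trace = mk.KineticTrace(
    time_s=t_s,
    signal=0.8 * np.exp(-2.242 * t) + 0.2 * np.exp(-0.340 * t),
    signal_kind="fraction_unfolded", condition=cond,
)
fit = mk.select_model(trace)
print(fit.model, round(fit.k_u1, 3), round(fit.k_u2, 3))
```

prints

```
double 2.242 0.34
```

— the selector recognizes the biphasic decay and the fitter returns the fast
(barrel-unfolding) and slow (aggregation) rate constants in min⁻¹. Running
`python examples/04_arrhenius.py` continues the story:

```
Eact = 16.54 kcal/mol  (slope = -8324 K)
linear: True  (quadratic term adds no information)
```

Each script in `examples/` exercises one capability (simulation, kinetic
fitting, melt fitting, Arrhenius analysis, the full pipeline) and prints a
line or two explaining its numbers.

## Command line

```bash
meltkin simulate     --out data/ --seed 17          # synthetic study + manifest
meltkin fit-kinetics --input data/ --dead-time 30 --out rates.json
meltkin fit-tscan    --input data/tscan_WT_5mM.csv --out tm.json
meltkin arrhenius    --rates rates.json --out eact.json
meltkin report       --input data/ --out report/    # all tables at once
```

Exit codes: 0 success, 2 configuration error, 3 data error.

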