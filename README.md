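# slowbind

Simulation and analysis of **slow-binding, covalent-reversible enzyme
inhibition kinetics**, built around the assay designs used to characterize
nanomolar peptidyl-ketoamide inhibitors of rhomboid intramembrane proteases
(e.g. *E. coli* GlpG). It is aimed at enzymologists and medicinal chemists
who need to turn fluorogenic progress curves, steady-state rate grids, IC50
screens, gel quantifications and jump-dilution experiments into mechanism-
level constants — kon, koff, Kiapp, the true Ki and the inhibition modality.

## The model

A slow-binding reversible inhibitor makes product-formation curves biphasic:

```
[P](t) = vs·t + (vi − vs)/kobs · (1 − exp(−kobs·t))
```

where `vi` and `vs` are the initial and steady-state rates and `kobs` is the
observed rate of onset of inhibition. For a one-step mechanism
(E + I ⇌ EI with slow kon, koff),

```
kobs = koff + kon_eff·[I],        Kiapp = koff / kon_eff
```

is affine in `[I]`; a hyperbolic dependence
`kobs = k6 + k5·[I]/(Ki1 + [I])` instead signals a two-step mechanism with
an EI ⇌ EI\* isomerization. The substrate correction `kon_eff` depends on
the modality (competitive: `kon/(1+S/Km)`; pure noncompetitive, α = 1:
`kon`; uncompetitive: `kon/(1+Km/S)`). Modality itself is inferred by
globally fitting steady-state rates over a substrate × inhibitor grid to
the four classical reversible-inhibition models and selecting by corrected
AIC. For pure noncompetitive inhibition the true Ki equals Kiapp and the
steady-state IC50 equals Ki at any substrate concentration.

## Layout

| module | what it does |
|---|---|
| `slowbind.schemes` | domain types: `KineticScheme`, `AssayDesign`, `NoiseModel`, `ProgressCurve` |
| `slowbind.simulate` | closed-form and ODE progress-curve simulators, noise, jump dilutions |
| `slowbind.progress` | biphasic (vi/vs/kobs) fits with a linearity guard |
| `slowbind.rates` | kobs–[I] regression → kon, koff, Kiapp; one- vs two-step selection; vi-independence test |
| `slowbind.modality` | global four-model Michaelis fitting, Ki↔Kiapp↔IC50 conversions |
| `slowbind.doseresponse` | 4-parameter-logistic IC50s, band-intensity conversion, knockout background correction, ABP competition |
| `slowbind.dilution` | jump-dilution reversibility classification |
| `slowbind.io` / `slowbind.cli` | CSV/YAML I/O, end-to-end pipeline, `slowbind` command |

## Worked example

Simulate the canonical slow-binding experiment (0.5 nM enzyme, 25 μM
fluorogenic substrate, a 1:3 inhibitor dilution series from 1,333 nM,
2 h curves, 1% signal noise) with the published compound-10 constants
(Kiapp 123 nM, koff 4.2×10⁻³ min⁻¹) and recover the constants:

```python
import slowbind as sb
from slowbind import benchmarks
from slowbind.io import ExperimentConfig

cfg = ExperimentConfig(
    scheme=sb.reference.compound_scheme("10", use_kiapp=True),
    design=benchmarks.slow_binding_design(),
    noise=sb.NoiseModel(sigma_rel=0.01, seed=7),
    options={"weighted_kobs": True},
)
print(sb.run_pipeline(cfg).to_text())
```

```
slowbind pipeline report (config e25e2a9d652ff0e3, seed 7)
stages: simulate, progress_fit, rate_analysis
kobs-[I] linear regression:
  kon  = 3.43e-05 +/- 8.3e-07 nM^-1 min^-1
  koff = 0.004249 +/- 0.00086 min^-1
  Kiapp = koff/kon = 123.9 +/- 28 nM
binding-model selection: one_step_linear (dAICc = -inf)
vi vs [I]: slope 1.05e-07, p = 0.475 -> independent
```

Reading: each simulated curve was fitted to the biphasic law; the kobs
values rise linearly with [I] (one-step slow binding selected), the initial
rate is statistically independent of [I] as expected for a slow binder, and
the regression recovers the generating constants — slope kon ≈ 3.4×10⁻⁵
nM⁻¹min⁻¹, intercept koff ≈ 4.2×10⁻³ min⁻¹, hence Kiapp ≈ 124 nM against
the generating 123 nM.

The same machinery is exposed on the command line:

```sh
slowbind simulate --config cfg.yaml --out curves.csv
slowbind fit-kobs --curves curves.csv --weighted --out kobs.json
slowbind report --config cfg.yaml --out report.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the two headline recovery studies from
scratch: the median Kiapp recovered by the full progress-curve pipeline on
the compound-10 design (25 seeds, 2% noise), and the median true Ki with
modality selection on a noncompetitive steady-state grid generated with the
compound-11 constants (25 seeds, 3% noise):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
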