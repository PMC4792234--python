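# micalkin

Steady-state kinetic analysis of F-actin-activated NADPH oxidation by MICAL
flavoenzyme constructs, and solution-mass estimation from size-exclusion
chromatography and small-angle X-ray scattering.

MICAL oxidises methionine residues of filamentous actin using NADPH; actin is
not required for turnover but accelerates it, i.e. it behaves as a
**non-essential activator**. The package exists for people who measure NADPH
oxidation velocities over a substrate × activator grid and want to quantify
*how* an accessory domain (here the calponin-homology, CH, domain) couples
actin binding to catalysis — and for checking such an analysis end to end on
synthetic data with known ground truth.

## The model

Four enzyme species (E, ES, EA, EAS) are assumed to be in rapid equilibrium,
with substrate dissociation constant K_M, activator dissociation constant
K_A, a coupling factor α that rescales both constants in the ternary branch,
and an acceleration factor β on the ternary turnover:

```
            E·kcat·(S/K_M)·(1 + β·A/(α·K_A))
v  =  ─────────────────────────────────────────────
       1 + S/K_M + A/K_A + S·A/(α·K_M·K_A)
```

At fixed activator concentration this collapses to an apparent
Michaelis–Menten law with

```
kcat_app(A) = kcat·(1 + β·A/(α·K_A)) / (1 + A/(α·K_A))
K_M_app(A)  = K_M ·(1 + A/K_A)       / (1 + A/(α·K_A))
```

α = 1 means actin does not change NADPH affinity (the isolated MO domain);
α < 1 means binding one ligand tightens the other (α = 0.16 for the MO-CH
construct — the CH domain couples actin binding to the active site). Whether
α differs from 1 is decided by fitting the grid globally with α free and
with α pinned to 1 and comparing the two nested fits with an
extra-sum-of-squares F-test.

Mass metrics: SEC masses come from a log10(Mw) vs Ve/Vo standard curve;
SAXS masses from the forward-scattering ratio against a standard
(I(0)/c ∝ Mw) and from the volume of correlation,
Vc = I(0)/∫q·I(q)dq, via Mw = (Vc²/Rg)/1.231. Guinier fits supply I(0) and
Rg; a Debye-sum generator builds profiles from point clouds so the whole
chain is testable against exact geometry.

## Worked example

Simulate the MO-CH assay design (NADPH 10–150 µM × F-actin 0–8 µM, 3
replicates, 3 % velocity noise, 0.6 µM enzyme) from the published global
parameters and re-fit it:

```python
from dataclasses import replace
from micalkin import NonEssentialActivatorModel, generate_dataset
from micalkin.presets import DESIGN_MO_CH, PARAMS_MO_CH

ds = generate_dataset(PARAMS_MO_CH, replace(DESIGN_MO_CH, seed=1))
m = NonEssentialActivatorModel(ds)
free = m.fit()
fixed = m.fit(fix_alpha=1.0)
print(free.summary())
print(free.compare_f_test(fixed))
```

```
Model: global_alpha_free
N obs: 60   RSS: 0.886439   dof: 55   converged: True
parameter      estimate      std err
k_cat            1.6614       0.1093
K_M              35.546       4.4007
K_act            10.212       2.3935
alpha           0.17736     0.051246
beta             7.7804      0.59806
F(1, 55) = 44.88, p = 1.171e-08
```

The fit recovers the generating parameters (k_cat = 1.7 s⁻¹, K_M = 37.7 µM,
K_A = 10.5 µM, α = 0.16, β = 7.43) within their standard errors, and the
F-test firmly rejects the no-coupling (α = 1) model — the inference the
analysis is built to support. The same workflow is available from the shell:

```
micalkin simulate --config design.yaml --out sim/
micalkin report --data sim/rates.csv --out report/
micalkin mass guinier --profile profile.dat
```

`micalkin report` also prints the per-actin apparent constants with the
catalytic-power row (1000·kcat_app/K_M_app, s⁻¹ mM⁻¹) rounded as in
publication tables.

## Acceptance script

`scripts/acceptance.py` regenerates the headline check from scratch: it
simulates velocities at the published MO-CH design with the published
parameters as ground truth, fits the five-parameter model with α free, and
writes the recovered coupling factor α to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `micalkin.kinetics` — rate law, apparent constants, catalytic power
- `micalkin.assay` — progress-curve simulation, initial-rate extraction, replicate dataset generation
- `micalkin.models` — model/results objects, global and apparent fits, F-test
- `micalkin.mass` — SEC calibration, Guinier, Vc and I(0)-ratio estimators, Debye toy profiles
- `micalkin.presets` — published parameter sets, assay designs and reference masses
- `micalkin.cli` — the `micalkin` command

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
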