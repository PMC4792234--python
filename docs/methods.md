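# Methods

## Kinetic model

The rate law is the rapid-equilibrium treatment of a non-essential activator
(Segel's general modifier scheme restricted to pure activation). Species E,
ES, EA and EAS equilibrate fast relative to turnover; detailed balance makes
the two routes to EAS share one coupling factor α, so the free parameters
are k_cat (s⁻¹), K_M (µM, NADPH), K_act (µM, F-actin), α (dimensionless,
> 0) and β (dimensionless, ≥ 0). Steady-state velocity:

v = E·k_cat·(S/K_M)·(1 + β·A/(α·K_act)) / (1 + S/K_M + A/K_act + S·A/(α·K_M·K_act))

Assumptions worth keeping in mind:

- **Rapid equilibrium, not steady-state binding.** K_M and K_act are true
  dissociation constants, valid when chemistry is rate-limiting.
- **Non-limiting ligands.** Free ≈ total concentrations for S and A; fine at
  0.6 µM enzyme against µM-to-hundred-µM ligands, questionable if enzyme
  were comparable to K_act.
- **F-actin enters as a molar monomer concentration.** Filament length,
  cooperative decoration and actin's own consumption as an oxidation
  substrate are outside the model (the simulator can deplete the activator,
  see below, but the fitted model assumes constant A).
- α = β = 1 reduces the law exactly to Michaelis–Menten, which the tests
  assert; apparent constants at fixed A are
  k_cat_app = k_cat(1+βA/(αK_act))/(1+A/(αK_act)),
  K_M_app = K_M(1+A/K_act)/(1+A/(αK_act)).

Catalytic power is 1000·k_cat_app/K_M_app (s⁻¹ mM⁻¹). Report tables round
half-away-from-zero to one decimal, which matches how published tables of
this kind are rounded. Default parameter presets (`micalkin.presets`) carry
the published global fits for the two constructs: MO
(0.68 s⁻¹, 28.8 µM, 9.3 µM, α=1, β=4.7) and MO-CH
(1.7 s⁻¹, 37.7 µM, 10.5 µM, α=0.16, β=7.43).

## Synthetic assays

`generate_dataset` emulates the replicate initial-rate experiment: for each
condition on the substrate × activator grid it perturbs the closed-form
velocity multiplicatively, v·(1 + cv·z), z ~ N(0,1), cv defaulting to 3 %.
Multiplicative noise reproduces the roughly constant *relative* error bars
such assays show. The design seed is expanded per condition through
`SeedSequence([seed, condition_index])`, so datasets are bit-reproducible
and insensitive to iteration order. Negative draws are clipped at zero
(essentially never at 3 % CV).

Default designs: 0.6 µM enzyme, 3 replicates; MO: NADPH
{3, 6, 12, 25, 50, 100} µM × actin {0, 0.45, 0.9, 2.2, 7.5} µM; MO-CH:
NADPH {10, 25, 50, 100, 150} µM × actin {0, 2, 4, 8} µM. The MO NADPH
interior levels are a choice (only the 3–100 µM span and the count of six
are stated for the original experiment); roughly log-spaced levels are what
one would run.

`simulate_trace` integrates dS/dt = −v(S, A) with classic fixed-step RK4
(dt = 0.05 s default; accuracy is validated against dt/10 re-integration at
1e-4 relative) and converts to A340 with ε₃₄₀ = 6220 M⁻¹cm⁻¹ and a 1 cm
path (standard values, both configurable). With `deplete_activator` the
activator is consumed at 1/`nadph_per_site` of the NADPH rate (default 1:1,
a simulation knob — the true stoichiometry of actin site consumption is an
open question), producing the early two-phase curvature seen at
sub-stoichiometric actin. `extract_initial_rate` takes the OLS slope of the
trace in a window, by default the 5–10 s read-out used experimentally.

What a green test does *not* establish: the generator has no mixing dead
time, no photobleaching or baseline drift, no correlated replicate error and
no actin polymerisation dynamics. Note also a real bias the simulator
reproduces faithfully: at low substrate and high actin, a few percent of the
NADPH is consumed before and during the 5–10 s window, so window slopes
underestimate true initial velocities by up to ~8 % at the extreme MO
condition. The pipeline-accuracy tests therefore use an early
[0, 0.1] s window; analyses of real traces inherit the experimental
window's bias.

## Fitting and inference

`MichaelisMentenModel` fits (k_cat_app, K_M_app) per activator level;
`NonEssentialActivatorModel` fits all five parameters simultaneously, with
`fit(fix_alpha=...)` for restricted models. Both use bounded
trust-region-reflective least squares (scipy), tolerances 1e-12, bounds
α ∈ [1e-3, 1e3], β ∈ [0, 1e3], positive constants otherwise. Starting
values come from the data (zero-actin Michaelis–Menten fit, median actin
level for K_act, velocity gain for β); the default 8 multi-starts perturb
that seed log-uniformly in [1/3, 3]. On the designs above a single start
from the data-derived seed lands on the same optimum (asserted in tests),
so simulation studies use `n_starts=1`.

Standard errors are Gauss–Newton: diag((JᵀJ)⁻¹·rss/dof)^½ at the optimum —
the convention of mainstream curve-fitting software. Degenerate apparent
fits (velocities without substrate dependence push K_M outside the data's
range by 1000×) are flagged `converged=False` rather than raised. β is
unidentifiable without a zero-actin level and at least one non-zero level;
the model refuses such data on construction.

**Weighting.** The default objective is unweighted least squares. Because
the noise model is constant-CV (variance ∝ v²), unweighted residuals are
heteroscedastic, which is harmless for point estimates (measured median
bias < 1 % on the MO-CH design) but miscalibrates the nested F-test on
designs whose velocities span a ~40-fold range: the measured type-I error
was ~0.13 instead of 0.05. `weights="relative"` (inverse squared
condition-mean velocity) is the variance-matched choice under constant-CV
noise and restores calibration (measured ~0.06 at 400 seeds); it is what
the Monte-Carlo calibration tests use. `weights="sem"` (inverse squared
SEM) is provided for completeness but is itself badly miscalibrated with
only 3 replicates (SEM estimates with 2 degrees of freedom are too noisy
to serve as weights) — measured type-I ~0.29. Use it only with many
replicates.

The extra-sum-of-squares F-test is
F = ((RSS_r − RSS_f)/(dof_r − dof_f))/(RSS_f/dof_f) with p from the
F survival function; it requires nesting (checked via dof and RSS ordering
with relative tolerance 1e-8) and identical data (checked via a fingerprint
of the condition/velocity arrays).

## Mass metrics

- **SEC**: ordinary least squares of log10(Mw) on Ve/Vo over ≥ 2 standards;
  prediction is 10^(intercept + slope·Ve/Vo). Queries beyond 1.5× the
  calibrated span warn as extrapolations.
- **Guinier**: linear fit of ln I vs q² with a self-consistent q·Rg ≤ 1.3
  cutoff (community convention for globular particles; iterated from the
  lowest-q points until the selected window is stable). Requires ≥ 5 points
  and a decaying profile.
- **Volume of correlation**: Vc = I(0)/∫₀^qmax q·I(q)dq, trapezoidal on the
  measured grid plus the closed-form Guinier integral for the unmeasured
  0 → q_min head. Mass = (Vc²/Rg)/1.231 with the denominator treated as an
  opaque empirical constant for protein at typical q ranges; no attempt is
  made to re-derive its q-range dependence.
- **I(0) ratio**: mass = mass_std·(I0/c)/(I0_std/c_std); dimeric BSA
  (132 kDa) is the conventional standard.
- **Toy profiles**: Debye sum I(q) = ΣΣ sin(q·d_ij)/(q·d_ij) over a point
  cloud, computed via a chunked pairwise-distance histogram (default bin
  0.25 Å) so 10⁴-point clouds stay cheap; the histogram smearing is far
  below the Guinier-region tolerances used in tests. `coordinate_rg` gives
  the exact mass-weighted Rg for cross-checking.

## Numerical and design choices

- Units: µM and seconds internally everywhere; catalytic power s⁻¹ mM⁻¹;
  Å/Å⁻¹ and Da in the scattering code.
- JSON serialisation of fits keeps full double precision (round-trip
  lossless to 1e-12, asserted).
- The Monte-Carlo acceptance checks (type-I at 2000 seeds, power and
  coverage at 200 seeds) are sized to run in a couple of minutes on one
  CPU with `n_starts=1`; the multi-start default is exercised separately.
- Known limitations: no bootstrap or profile-likelihood intervals; no
  essential-activation or ternary-ordered mechanism variants; no substrate
  inhibition or oxygen dependence; SAXS code does no P(r) inversion, Porod
  volume or envelope modelling.
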