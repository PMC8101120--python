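# Methods

## Model

The package implements a three-state illness-death model: healthy → IBD
(onset), healthy → dead (background mortality), IBD → dead (patient
mortality). IBD is treated as chronic: there is no recovery transition, so
the prevalent pool only loses members through death. Two engines share one
parameterization.

*Deterministic engine.* The compartment counts follow the linear ODE system

    dH/dt = -(d + λ) H + B
    dI/dt = λ H - μ I
    dD/dt = d H + μ I

with cumulative deaths D tracked so that H + I + D − B·t is conserved
(checked to relative error 1e-8 along every trajectory). The system is
integrated with an adaptive solver (`scipy.integrate.solve_ivp`, LSODA,
rtol 1e-9, atol 1e-6 persons); the numerical path is kept even though a
closed form exists so that user-supplied birth series work unchanged.

*Stochastic engine.* The same hazards define a 3×3 one-step transition
matrix; the integer population is advanced annually by one multinomial draw
per compartment, which has exactly the finite-population demographic-noise
distribution of individual-level simulation at a fraction of the cost.
Replicates run on independent `numpy` substreams spawned from one master
seed and are reproducible bit-for-bit.

## Assumptions

- All hazards are constant over the projection window (2017–2035). This is
  the standard stage-three reading of IBD epidemiology in Asia: prevalence
  compounds even under flat incidence.
- No age or sex structure; each compartment is homogeneous. A
  partial-differential (age-structured) variant is out of scope.
- Death is absorbing; migration is ignored.

## Parameters and units

Printed inputs are per 100,000 per year; internal hazards are per capita
per year. For each region:

| quantity | symbol | source/derivation |
|---|---|---|
| onset hazard | λ | incidence / 1e5 |
| patient mortality | μ | IBD death rate / prevalence ratio |
| background mortality | d | other-cause death rate / 1e5 |
| total population | N | cases / prevalence ratio × 1e5 |
| birth inflow | B | closure (below) |

Two derivations deserve note. The printed IBD death rate is per 100,000
*total* population while the patient equation needs a hazard per patient;
dividing by the prevalence ratio (both per 100,000) gives deaths among
patients per patient, the dimensionally consistent choice. And because the
source analysis took population and births from demographic databases that
are not part of the packaged inputs, the population is back-derived from
the printed prevalence ratio, and the default birth closure is
**stationary-healthy**: B = (d + λ)·H0, held constant, so the healthy pool
is exactly replenished. Any constant B can be supplied instead. The
back-derived population is internally consistent with the printed
prevalence but need not match census totals (East Asia's implied 2.06 B is
the clearest case); all projections are driven by the product λH, which is
what the printed table pins down.

## Rate → probability conversion

The annual transition probabilities use competing-risks exponential
conversion: the healthy row is p_stay = e^(−(λ+d)dt), with the leaving mass
1 − p_stay split in proportion λ:d; the patient row is p_stay = e^(−μ dt).
This keeps every probability in [0,1] for any hazard magnitude and is
first-order identical to p = rate·dt at these magnitudes. The time step is
1 year, matching the annual reporting grid. Births are rounded to an
integer once and added to the healthy pool at the end of each step.

## Uncertainty band

The printed 95% uncertainty intervals are propagated by a corner rule: the
projection is run at every combination of interval endpoints for the
prevalence ratio, IBD death rate and background death rate (2³ corners plus
the point estimate) and the band is the pointwise min/max envelope. A single
"worst corner" cannot be chosen a priori because the prevalence ratio pushes
in two directions at once — a lower ratio raises the implied population
(more onsets) but raises per-patient mortality too — so the full envelope is
taken; it is conservative and makes no distributional assumption. Incidence
is printed without an interval and is held at its point value.

## Sensitivity analysis

Local normalized sensitivities (elasticities) ∂I(t)/∂θ · θ/I(t) are
computed by central finite differences with relative step 1e-3 (second
order: halving the step moves the estimates by < 1e-6). The birth inflow is
resolved once at base rates and held fixed while each hazard is perturbed,
so an onset perturbation is not silently compensated by the closure. Model
structure fixes the signs: positive for λ and B, negative for μ and d. For
the Iranian parameters at t = 18 the onset elasticity is 0.686 — the
closed-form value (a/μ)(1−e^(−μt))/I(t) — i.e. the 2035 caseload responds
slightly sublinearly to incidence because the inherited 2017 pool decays
independently of λ.

## Derived quantities

Doubling time from a reference year is the smallest elapsed time at which
I reaches twice its reference value, linearly interpolated between grid
years, with +∞ when not reached inside the horizon (the case for East Asia,
Southeast Asia and High-income Asia-Pacific by 2035). Fold change is the
plain ratio I(y2)/I(y1). Both are computed from trajectories, never from
prose-rounded figures.

## Synthetic data and parameter recovery

The generator draws region tables uniformly from stated ranges bracketing
the published values (incidence 0.5–10, prevalence 5–150, IBD death
0.05–0.5, background death 400–1000 per 100,000; population 10⁶–10⁹),
places symmetric ±10% interval bounds, and emits the same CSV schema the
loader reads. Observed prevalence series are one stochastic replicate
multiplied by independent mean-one lognormal noise with a stated
coefficient of variation (counts stay positive; the CV is scale-free; no
observation model is inherited from the source data, so the simplest
standard one is stated explicitly).

The recovery harness fits the onset rate by bounded 1-D least squares of
the closed-form trajectory against an observed series, all other rates
known. The headline study uses one generator-drawn region from the
large-population end of the range (10⁸–10⁹, so demographic noise is
negligible next to the 5% observation noise), 19 annual observations and
100 noise seeds; the median absolute relative error is ≈1–3% depending on
seed, typically under 2%. Recovery precision degrades for regions where
the λ-driven growth is small relative to the inherited prevalent pool
(high μ, low λ) — across fully heterogeneous generator draws the median
error rises to ≈2.5% — and this identifiability limit, not the optimizer,
dominates the error.

What the generator does *not* emulate: age/sex structure, time-varying
rates, reporting artifacts (diagnosis delays, coverage changes), or
migration. Passing tests therefore validate the pipeline's internal
consistency, not the realism of any particular published rate.

## Numerical choices

- ODE tolerances rtol 1e-9 / atol 1e-6 persons; integrator failure raises
  rather than returning a partial trajectory.
- Closed form vs. integrator agree to relative error < 1e-6 on all six
  packaged regions over the full grid; one frozen cross-check against an
  independent ODE solver (R deSolve, lsoda) guards the model assembly.
- Table I/O uses shortest round-tripping decimal formatting both ways, so
  write → read is lossless to the bit.
- Degenerate inputs: zero prevalent cases cannot back-derive a population
  and are rejected with instructions to pass an explicit state; λ+d = 0
  takes the p_stay = 1 branch; μ = 0 switches the closed form to its linear
  limit I0 + λH0·t.
- Reported units follow the published table: thousands of cases, 3
  decimals; raw persons available via a flag.

## Problem sizes

Default runs use the six-region table on the 2017–2035 annual grid, 200
stochastic replicates, 100 recovery seeds, and a 60-region synthetic smoke
battery; the full test suite completes in a few seconds on one CPU.

## Known limitations

- The published stochastic figures' summary statistic is unstated; the
  package reports the ensemble mean. For Iran the 200-replicate mean at
  2035 lands within ~1.5% of the published stochastic value.
- The published East Asia stochastic row (4.684 M by 2035) is inconsistent
  with its own deterministic row (3.155 M) and with any trajectory the
  printed East Asia rates generate; the package makes no attempt to
  reproduce it.
- Deterministic 2020 values for the five non-Iranian regions reproduce to
  within 2–7% under the stationary-healthy closure; the gap grows toward
  2035 because the original analysis drew region-specific birth numbers
  from demographic databases that are not among the printed inputs. Iran,
  whose published trajectory the closure reproduces to < 0.5% at every
  printed year, is the calibration anchor.
- Constant-hazard extrapolation ignores cohort effects, diagnostic-capacity
  trends and any intervention; projections are scenario arithmetic, not
  forecasts with calibrated uncertainty.
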