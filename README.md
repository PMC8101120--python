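# ibdforecast

Projection of inflammatory bowel disease (IBD) prevalence with a three-state
illness-death model, built for epidemiologists who need chronic-disease
burden forecasts from nothing more than a handful of published rates per
region. The package ships the 2017 literature-based parameter table for six
Asian regions (Iran, High-income Asia-Pacific, East Asia, Southeast Asia,
North Africa & Middle East, South Asia) and projects prevalent cases
annually to 2035 with two engines that share one parameterization:

**Deterministic.** People are healthy (H), have IBD (I), or are dead; IBD
is chronic, so there is no recovery transition. With onset hazard λ,
per-patient IBD mortality μ, background mortality d and birth inflow B,

```
dH/dt = -(d + λ) H + B
dI/dt = λ H - μ I
```

Under the default *stationary-healthy* closure (B chosen so the healthy pool
exactly replaces its annual losses) the patient equation has the closed form
I(t) = a/μ + (I0 − a/μ)·e^(−μt) with a = λH0, which the package uses as an
exact oracle for its numerical integrator.

**Stochastic.** The same hazards are converted to a 3×3 one-step Markov
matrix by competing-risks exponential conversion (death absorbing, no
recovery) and the integer population is advanced year by year with one
multinomial draw per compartment — exact demographic noise, reproducible
from a single master seed.

All printed rates are per 100,000 per year; the total population of a region
is back-derived from its prevalence ratio and prevalent-case count, so no
external demographic data are needed. A synthetic-data module generates
random region tables and noisy observed prevalence series, and a 1-D
least-squares harness recovers the onset rate from such a series.

## Worked example

```python
import ibdforecast as ib

iran = next(p for p in ib.load_builtin_table() if p.region_name == "Iran")
state0 = ib.derive_initial_state(iran)      # 23,812 cases, 88.2 M people
rates = ib.to_model_rates(iran)             # λ=3.11e-5, μ=0.16/27, d=4.64e-3

traj = ib.integrate(state0, rates, horizon_years=18)
print(round(traj.ibd_at(2035)))             # 68218
print(round(ib.doubling_time(traj, 2020), 1))   # 12.8
print(round(ib.fold_change(traj, 2020, 2035), 2))  # 2.16
```

The projected Iranian caseload grows from 23,812 (2017) to 68,218 (2035)
prevalent cases — within 0.02% of the published deterministic figure of
68.207 thousand — doubling its 2020 value in about 12.8 years. The
stochastic counterpart:

```python
import dataclasses
s = dataclasses.replace(state0, healthy=round(state0.healthy), ibd=round(state0.ibd))
ens = ib.simulate(s, rates, horizon_years=18, replicates=200, master_seed=1)
print(round(ens.ibd_at(2035).mean()))       # 68256
```

Or from the shell:

```
ibdforecast project --approach both --seed 1 --out out/
```

which writes `projections.csv` (region, approach, year, cases in thousands)
and `summary.json` with doubling times and fold changes per region.

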