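"""Deterministic illness-death ODE model of chronic-disease prevalence.

The two-compartment linear system

    dH/dt = -(d + lambda) * H + B
    dI/dt = lambda * H - mu * I

with healthy pool H, patient pool I, background mortality d, onset hazard
lambda, per-patient mortality mu and constant birth inflow B.  Deaths are
tracked cumulatively (dD/dt = d*H + mu*I) so that the bookkeeping identity
H + I + D = total(0) + B*t holds along the whole trajectory.

Under the stationary-healthy closure (B chosen so dH/dt = 0) the patient
equation decouples and has the closed form

    I(t) = a/mu + (I0 - a/mu) * exp(-mu * t),    a = lambda * H0,

which serves as an exact oracle for the numerical integrator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    STATIONARY_HEALTHY,
    CompartmentState,
    ModelRates,
    RegionParameters,
    ValidationError,
    derive_initial_state,
    to_model_rates,
)

__all__ = [
    "Trajectory",
    "IntervalProjection",
    "SensitivityResult",
    "ode_rhs",
    "integrate",
    "closed_form_prevalence",
    "project_interval",
    "sensitivity",
    "doubling_time",
    "fold_change",
]

RTOL = 1e-9
ATOL = 1e-6  # persons; populations here are 1e4..1e9


@dataclass(frozen=True)
class Trajectory:
    """Deterministic time series on a calendar-year grid."""

    grid: np.ndarray          # calendar years, strictly increasing
    healthy: np.ndarray
    ibd: np.ndarray
    dead_cum: np.ndarray
    rates_used: ModelRates    # with birth_inflow resolved to a constant
    closure_used: str

    def state_at(self, year: float) -> CompartmentState:
        i = self._index(year)
        return CompartmentState(
            year=float(self.grid[i]),
            healthy=float(self.healthy[i]),
            ibd=float(self.ibd[i]),
            dead_cum=float(self.dead_cum[i]),
        )

    def ibd_at(self, year: float) -> float:
        return float(self.ibd[self._index(year)])

    def _index(self, year: float) -> int:
        hits = np.nonzero(np.isclose(self.grid, year, rtol=0.0, atol=1e-9))[0]
        if hits.size == 0:
            raise KeyError(f"year {year} is not on the trajectory grid")
        return int(hits[0])


@dataclass(frozen=True)
class IntervalProjection:
    """Pointwise envelope of patient counts over the printed UI bounds."""

    grid: np.ndarray
    ibd_point: np.ndarray
    ibd_low: np.ndarray
    ibd_high: np.ndarray


@dataclass(frozen=True)
class SensitivityResult:
    """Normalized local sensitivities (elasticities) of the patient count.

    ``elasticities[name]`` = (dI(t)/d theta) * theta / I(t), a dimensionless
    measure of how strongly the projection responds to each hazard.
    """

    t: float
    rel_perturbation: float
    elasticities: dict[str, float]


def ode_rhs(state: Sequence[float], rates: ModelRates, births: float) -> tuple[float, float, float]:
    """Time derivatives (dH/dt, dI/dt, dD/dt) of the illness-death system."""
    h, i = float(state[0]), float(state[1])
    dh = -(rates.d_background + rates.lambda_inc) * h + births
    di = rates.lambda_inc * h - rates.mu_ibd * i
    dd = rates.d_background * h + rates.mu_ibd * i
    return dh, di, dd


def integrate(
    state0: CompartmentState,
    rates: ModelRates,
    horizon_years: float,
    output_step: float = 1.0,
) -> Trajectory:
    """Integrate the ODE system from ``state0`` over ``horizon_years``.

    Returns the solution on the grid ``state0.year + k*output_step``.  The
    solver is adaptive (LSODA) with tight relative tolerance; a step failure
    raises rather than returning a partial trajectory.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    if output_step <= 0:
        raise ValueError("output_step must be > 0")
    births = rates.resolve_births(state0.healthy)
    closure = (
        STATIONARY_HEALTHY if rates.birth_inflow == STATIONARY_HEALTHY
        else "constant-births"
    )
    n_steps = int(math.floor(horizon_years / output_step + 1e-9))
    grid_rel = np.arange(n_steps + 1) * output_step
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, rates, births),
        (0.0, float(horizon_years)),
        [state0.healthy, state0.ibd, state0.dead_cum],
        method="LSODA",
        t_eval=grid_rel,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(
        grid=state0.year + grid_rel,
        healthy=sol.y[0],
        ibd=sol.y[1],
        dead_cum=sol.y[2],
        rates_used=rates.with_births(births),
        closure_used=closure,
    )


def closed_form_prevalence(
    state0: CompartmentState, rates: ModelRates, t: float
) -> float:
    """Exact patient count at elapsed time ``t`` under the stationary closure.

    Requires the stationary-healthy closure (H constant at H0).  Returns
    a/mu + (I0 - a/mu) * exp(-mu t) with a = lambda * H0, or I0 + a*t when
    mu = 0.
    """
    if rates.birth_inflow != STATIONARY_HEALTHY:
        raise ValueError(
            "closed form holds only under the stationary-healthy closure"
        )
    a = rates.lambda_inc * state0.healthy
    if rates.mu_ibd == 0.0:
        return state0.ibd + a * t
    eq = a / rates.mu_ibd
    return eq + (state0.ibd - eq) * math.exp(-rates.mu_ibd * t)


def _corner_rates(p: RegionParameters) -> list[tuple[str, ModelRates, CompartmentState]]:
    """ModelRates/initial-state pairs at every UI corner plus the point.

    The prevalence bound changes both the implied population and the
    per-patient mortality, so corners carry their own initial states.
    """
    combos = [("point", "point", "point")]
    combos += list(itertools.product(["ui_low", "ui_high"], repeat=3))
    out = []
    for prev_w, ibd_w, bg_w in combos:
        prev = p.prevalence_ratio.bound(prev_w)
        ibd_death = p.ibd_death_rate.bound(ibd_w)
        bg = p.background_death_rate.bound(bg_w)
        rates = ModelRates(
            lambda_inc=p.incidence_rate / 100_000.0,
            mu_ibd=0.0 if ibd_death == 0 else ibd_death / prev,
            d_background=bg / 100_000.0,
        )
        total = p.initial_prevalent_cases / prev * 100_000.0
        st = CompartmentState(
            year=float(p.start_year),
            healthy=total - p.initial_prevalent_cases,
            ibd=p.initial_prevalent_cases,
        )
        out.append((f"{prev_w}/{ibd_w}/{bg_w}", rates, st))
    return out


def project_interval(
    p: RegionParameters, horizon_years: float, output_step: float = 1.0
) -> IntervalProjection:
    """Uncertainty band on the projection from the printed 95% UI bounds.

    The point trajectory uses point rates; the band is the pointwise min/max
    envelope of trajectories run at every combination of UI corner values
    (a conservative corner rule — no distributional assumption on the UIs).
    """
    if p.prevalence_ratio.ui_low <= 0:
        raise ValidationError(
            f"region {p.region_name!r}: UI bounds must be positive for projection"
        )
    trajs = {}
    for label, rates, st in _corner_rates(p):
        trajs[label] = integrate(st, rates, horizon_years, output_step)
    point = trajs["point/point/point"]
    stack = np.vstack([t.ibd for t in trajs.values()])
    return IntervalProjection(
        grid=point.grid,
        ibd_point=point.ibd,
        ibd_low=stack.min(axis=0),
        ibd_high=stack.max(axis=0),
    )


def sensitivity(
    p: RegionParameters,
    t: float,
    rel_perturbation: float = 1e-3,
    which: str = "point",
) -> SensitivityResult:
    """Central finite-difference elasticities of I(t) w.r.t. each hazard.

    The birth inflow is resolved once at the base rates and held fixed while
    each hazard is perturbed, so an incidence perturbation is not silently
    compensated by the closure.  Model structure implies the elasticity
    w.r.t. onset is >= 0 and w.r.t. patient mortality is <= 0.
    """
    if not (0.0 < rel_perturbation < 0.5):
        raise ValueError("rel_perturbation must be a small positive fraction")
    state0 = derive_initial_state(p)
    base = to_model_rates(p, which)
    births = base.resolve_births(state0.healthy)
    base = base.with_births(births)

    def ibd_at_t(rates: ModelRates) -> float:
        return integrate(state0, rates, t, t).ibd_at(state0.year + t)

    i_base = ibd_at_t(base)
    if i_base <= 0:
        raise ValidationError("I(t) = 0: elasticities undefined")
    out: dict[str, float] = {}
    for name in ("lambda_inc", "mu_ibd", "d_background", "birth_inflow"):
        theta = getattr(base, name)
        if theta == 0.0:
            out[name] = 0.0
            continue
        h = theta * rel_perturbation
        lo = {name: theta - h}
        hi = {name: theta + h}
        from dataclasses import replace
        i_hi = ibd_at_t(replace(base, **hi))
        i_lo = ibd_at_t(replace(base, **lo))
        out[name] = (i_hi - i_lo) / (2.0 * h) * theta / i_base
    return SensitivityResult(t=t, rel_perturbation=rel_perturbation, elasticities=out)


def doubling_time(traj: Trajectory, ref_year: float) -> float:
    """Years until the patient count first reaches twice its ref-year value.

    Linear interpolation between grid points; ``math.inf`` if doubling is
    not reached within the trajectory horizon.
    """
    i_ref = traj.ibd_at(ref_year)  # KeyError if off-grid
    if i_ref <= 0:
        raise ValidationError("reference-year patient count must be > 0")
    target = 2.0 * i_ref
    mask = traj.grid >= ref_year - 1e-9
    years = traj.grid[mask]
    vals = traj.ibd[mask]
    for k in range(1, len(vals)):
        if vals[k] >= target:
            y0, y1 = years[k - 1], years[k]
            v0, v1 = vals[k - 1], vals[k]
            if v1 == v0:
                return float(y1 - ref_year)
            frac = (target - v0) / (v1 - v0)
            return float(y0 + frac * (y1 - y0) - ref_year)
    return math.inf


def fold_change(traj: Trajectory, y1: float, y2: float) -> float:
    """Ratio of patient counts I(y2) / I(y1) on the trajectory grid."""
    denom = traj.ibd_at(y1)
    if denom <= 0:
        raise ValidationError(f"I({y1}) = 0: fold change undefined")
    return traj.ibd_at(y2) / denom
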