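"""Stochastic counterpart of the illness-death model.

A 3x3 one-step Markov matrix over (healthy, ibd, dead) is built from the
per-capita hazards by competing-risks exponential conversion, and the
population is advanced in annual steps by one multinomial draw per
compartment (exact finite-population demographic noise).  Death is
absorbing and patients do not recover.  Replicates use independent
substreams spawned from a single master seed, so an ensemble is
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CompartmentState, ModelRates, ValidationError

__all__ = [
    "MarkovMatrix",
    "EnsembleTrajectory",
    "build_transition_matrix",
    "step",
    "simulate",
    "expected_trajectory",
    "summarize",
]

HEALTHY, IBD, DEAD = 0, 1, 2
_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MarkovMatrix:
    """Row-stochastic one-step transition matrix over (healthy, ibd, dead)."""

    probs: np.ndarray  # shape (3, 3)
    dt: float

    def __post_init__(self) -> None:
        m = self.probs
        if m.shape != (3, 3):
            raise ValidationError("transition matrix must be 3x3")
        if np.any(m < 0) or np.any(m > 1):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValidationError("every row must sum to 1")
        if not np.array_equal(m[DEAD], [0.0, 0.0, 1.0]):
            raise ValidationError("dead state must be absorbing")
        if m[IBD, HEALTHY] != 0.0:
            raise ValidationError("recovery transition ibd->healthy must be 0")


@dataclass(frozen=True)
class EnsembleTrajectory:
    """Replicate-indexed integer trajectories with seed metadata.

    Arrays have shape (replicates, years+1); column k is the state at the
    start of year ``grid[k]``.
    """

    grid: np.ndarray       # integer calendar years
    healthy: np.ndarray
    ibd: np.ndarray
    dead_cum: np.ndarray
    master_seed: int
    births_per_year: int

    @property
    def n_replicates(self) -> int:
        return self.ibd.shape[0]

    def ibd_at(self, year: int) -> np.ndarray:
        hits = np.nonzero(self.grid == year)[0]
        if hits.size == 0:
            raise KeyError(f"year {year} is not on the ensemble grid")
        return self.ibd[:, int(hits[0])]


def build_transition_matrix(rates: ModelRates, dt: float = 1.0) -> MarkovMatrix:
    """One-step transition probabilities from competing exponential risks.

    For the healthy row the two hazards (onset lambda, background death d)
    compete: survival is exp(-(lambda+d) dt) and the leaving mass is split
    in proportion to the hazards.  This keeps every probability in [0, 1]
    for any hazard magnitudes, unlike the naive p = rate * dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    lam, d, mu = rates.lambda_inc, rates.d_background, rates.mu_ibd
    total = lam + d
    if total == 0.0:
        p_hh, p_hi, p_hd = 1.0, 0.0, 0.0
    else:
        stay = math.exp(-total * dt)
        leave = 1.0 - stay
        p_hh, p_hi, p_hd = stay, lam / total * leave, d / total * leave
    p_ii = math.exp(-mu * dt)
    m = np.array([
        [p_hh, p_hi, p_hd],
        [0.0, p_ii, 1.0 - p_ii],
        [0.0, 0.0, 1.0],
    ])
    # guard against rounding in the assembled rows
    m[0, 2] = 1.0 - m[0, 0] - m[0, 1]
    return MarkovMatrix(probs=m, dt=dt)


def step(
    state: CompartmentState,
    matrix: MarkovMatrix,
    births: int,
    rng: np.random.Generator,
) -> CompartmentState:
    """Advance the population one step: multinomial draws plus birth inflow.

    Conservation is exact in integers: occupants leaving each compartment
    are reallocated, never created or destroyed; births (already integer)
    enter the healthy pool at the end of the step.
    """
    state.require_integer()
    if births < 0:
        raise ValidationError("births must be >= 0")
    from_h = rng.multinomial(int(state.healthy), matrix.probs[HEALTHY])
    from_i = rng.multinomial(int(state.ibd), matrix.probs[IBD])
    return CompartmentState(
        year=state.year + matrix.dt,
        healthy=int(from_h[HEALTHY]) + int(births),
        ibd=int(from_h[IBD]) + int(from_i[IBD]),
        dead_cum=int(state.dead_cum) + int(from_h[DEAD]) + int(from_i[DEAD]),
    )


def simulate(
    state0: CompartmentState,
    rates: ModelRates,
    horizon_years: int,
    replicates: int = 200,
    master_seed: int = 0,
) -> EnsembleTrajectory:
    """Monte-Carlo ensemble of annual trajectories.

    Each replicate runs on an independent substream spawned from
    ``master_seed``; the same seed reproduces the ensemble exactly.  The
    birth inflow is resolved from the configured closure, rounded to an
    integer once, and applied every year.
    """
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    state0.require_integer()
    matrix = build_transition_matrix(rates, dt=1.0)
    births = int(round(rates.resolve_births(state0.healthy)))
    streams = np.random.SeedSequence(master_seed).spawn(replicates)

    shape = (replicates, horizon_years + 1)
    healthy = np.empty(shape, dtype=np.int64)
    ibd = np.empty(shape, dtype=np.int64)
    dead = np.empty(shape, dtype=np.int64)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        s = state0
        healthy[r, 0], ibd[r, 0], dead[r, 0] = int(s.healthy), int(s.ibd), int(s.dead_cum)
        for k in range(1, horizon_years + 1):
            s = step(s, matrix, births, rng)
            healthy[r, k], ibd[r, k], dead[r, k] = int(s.healthy), int(s.ibd), int(s.dead_cum)
    grid = np.arange(horizon_years + 1, dtype=np.int64) + int(state0.year)
    return EnsembleTrajectory(
        grid=grid, healthy=healthy, ibd=ibd, dead_cum=dead,
        master_seed=master_seed, births_per_year=births,
    )


def expected_trajectory(
    state0: CompartmentState, rates: ModelRates, horizon_years: int
) -> np.ndarray:
    """Discrete-time expectation of the annual update (mean-field recursion).

    Returns the expected patient count per year, the quantity the ensemble
    mean converges to as replicates grow.  Differs from the continuous ODE
    only by the annual discretization.
    """
    matrix = build_transition_matrix(rates, dt=1.0).probs
    births = round(rates.resolve_births(state0.healthy))
    h, i = float(state0.healthy), float(state0.ibd)
    out = [i]
    for _ in range(horizon_years):
        h, i = (
            h * matrix[HEALTHY, HEALTHY] + births,
            h * matrix[HEALTHY, IBD] + i * matrix[IBD, IBD],
        )
        out.append(i)
    return np.asarray(out)


def summarize(
    ensemble: EnsembleTrajectory, quantiles: tuple[float, ...] = ()
) -> pd.DataFrame:
    """Per-year ensemble mean (and optional empirical quantiles) of patients."""
    for q in quantiles:
        if not (0.0 < q < 1.0):
            raise ValueError(f"quantile {q} outside (0, 1)")
    data = {"year": ensemble.grid, "ibd_mean": ensemble.ibd.mean(axis=0)}
    for q in quantiles:
        data[f"ibd_q{q:g}"] = np.quantile(ensemble.ibd, q, axis=0)
    return pd.DataFrame(data)
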