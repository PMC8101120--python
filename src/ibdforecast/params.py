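"""Region parameter tables, unit conversion, and initial-state construction.

Printed epidemiological rates (per 100,000 per year) are converted to the
per-capita annual hazards the illness-death model runs on.  The total
population of a region is back-derived from its prevalence ratio and its
prevalent-case count, so the module needs no external demographic inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import pandas as pd

__all__ = [
    "PER_100K",
    "STATIONARY_HEALTHY",
    "SchemaError",
    "ValidationError",
    "Uncertain",
    "RegionParameters",
    "ModelRates",
    "CompartmentState",
    "load_region_table",
    "write_region_table",
    "load_builtin_table",
    "derive_initial_state",
    "to_model_rates",
]

PER_100K = 100_000.0

#: Symbolic birth-inflow closure: births replace the healthy pool's annual
#: losses, B = (d + lambda) * healthy(start), held constant thereafter.
STATIONARY_HEALTHY = "stationary-healthy"

TABLE_COLUMNS = [
    "region",
    "incidence",
    "prev", "prev_lo", "prev_hi",
    "ibd_death", "ibd_death_lo", "ibd_death_hi",
    "bg_death", "bg_death_lo", "bg_death_hi",
    "initial_cases",
    "start_year",
]


class SchemaError(ValueError):
    """A table is missing a required column."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class Uncertain:
    """A point estimate with a 95% uncertainty interval."""

    point: float
    ui_low: float
    ui_high: float

    def __post_init__(self) -> None:
        if not (self.ui_low <= self.point <= self.ui_high):
            raise ValidationError(
                f"inverted uncertainty interval: low={self.ui_low}, "
                f"point={self.point}, high={self.ui_high}"
            )

    def bound(self, which: Literal["point", "ui_low", "ui_high"]) -> float:
        if which not in ("point", "ui_low", "ui_high"):
            raise ValueError(f"unknown bound selector {which!r}")
        return getattr(self, which)

    @classmethod
    def exact(cls, value: float) -> "Uncertain":
        return cls(value, value, value)


@dataclass(frozen=True)
class RegionParameters:
    """One region's printed rates (per 100,000/year) plus initial cases.

    ``incidence_rate`` is new cases per 100,000 person-years among the
    healthy; ``prevalence_ratio`` is prevalent cases per 100,000 persons;
    the two death rates are deaths per 100,000 total population per year,
    split into IBD-attributed and all-other-cause deaths.
    """

    region_name: str
    incidence_rate: float
    prevalence_ratio: Uncertain
    ibd_death_rate: Uncertain
    background_death_rate: Uncertain
    initial_prevalent_cases: float
    start_year: int = 2017

    def __post_init__(self) -> None:
        named = {
            "incidence_rate": self.incidence_rate,
            "prevalence_ratio": self.prevalence_ratio.ui_low,
            "ibd_death_rate": self.ibd_death_rate.ui_low,
            "background_death_rate": self.background_death_rate.ui_low,
            "initial_prevalent_cases": self.initial_prevalent_cases,
        }
        for fname, value in named.items():
            if value < 0:
                raise ValidationError(
                    f"region {self.region_name!r}: {fname} must be >= 0, got {value}"
                )
        if self.initial_prevalent_cases > 0 and self.prevalence_ratio.point <= 0:
            raise ValidationError(
                f"region {self.region_name!r}: prevalence_ratio must be positive "
                "when initial_prevalent_cases > 0 (population back-derivation)"
            )


@dataclass(frozen=True)
class ModelRates:
    """Per-capita annual transition hazards of the illness-death model.

    ``lambda_inc`` acts on the healthy compartment (onset), ``mu_ibd`` on
    patients (IBD mortality per patient), ``d_background`` on the healthy
    (all-other-cause mortality).  ``birth_inflow`` is either a constant
    persons/year or the symbolic closure :data:`STATIONARY_HEALTHY`.
    """

    lambda_inc: float
    mu_ibd: float
    d_background: float
    birth_inflow: Union[float, str] = STATIONARY_HEALTHY

    def __post_init__(self) -> None:
        for name in ("lambda_inc", "mu_ibd", "d_background"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(
                    f"{name} must be an annual per-capita hazard in [0, 1), got {v}"
                )
        if isinstance(self.birth_inflow, str):
            if self.birth_inflow != STATIONARY_HEALTHY:
                raise ValidationError(
                    f"unknown birth closure {self.birth_inflow!r}"
                )
        elif self.birth_inflow < 0:
            raise ValidationError("birth_inflow must be >= 0")

    def resolve_births(self, healthy0: float) -> float:
        """Constant annual birth inflow implied by the configured closure."""
        if self.birth_inflow == STATIONARY_HEALTHY:
            return (self.d_background + self.lambda_inc) * healthy0
        return float(self.birth_inflow)

    def with_births(self, births: float) -> "ModelRates":
        return replace(self, birth_inflow=float(births))


@dataclass(frozen=True)
class CompartmentState:
    """Snapshot (year, healthy, ibd, cumulative deaths) of the population."""

    year: float
    healthy: float
    ibd: float
    dead_cum: float = 0.0

    def __post_init__(self) -> None:
        if self.healthy < 0 or self.ibd < 0 or self.dead_cum < 0:
            raise ValidationError(
                f"compartments must be >= 0: healthy={self.healthy}, "
                f"ibd={self.ibd}, dead_cum={self.dead_cum}"
            )

    @property
    def total_alive(self) -> float:
        return self.healthy + self.ibd

    def require_integer(self) -> None:
        for name in ("healthy", "ibd", "dead_cum"):
            v = getattr(self, name)
            if float(v) != int(v):
                raise ValidationError(
                    f"stochastic state requires integer counts; {name}={v}"
                )


def _row_to_params(row: pd.Series) -> RegionParameters:
    return RegionParameters(
        region_name=str(row["region"]),
        incidence_rate=float(row["incidence"]),
        prevalence_ratio=Uncertain(
            float(row["prev"]), float(row["prev_lo"]), float(row["prev_hi"])
        ),
        ibd_death_rate=Uncertain(
            float(row["ibd_death"]), float(row["ibd_death_lo"]), float(row["ibd_death_hi"])
        ),
        background_death_rate=Uncertain(
            float(row["bg_death"]), float(row["bg_death_lo"]), float(row["bg_death_hi"])
        ),
        initial_prevalent_cases=float(row["initial_cases"]),
        start_year=int(row["start_year"]),
    )


def load_region_table(path: Union[str, Path]) -> list[RegionParameters]:
    """Read a CSV region-parameter table and validate every row.

    Expected header: ``region, incidence, prev, prev_lo, prev_hi, ibd_death,
    ibd_death_lo, ibd_death_hi, bg_death, bg_death_lo, bg_death_hi,
    initial_cases, start_year`` — rates per 100,000 per year.  Invariant
    violations raise :class:`ValidationError` naming region and field;
    missing columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"region table {path} is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(_row_to_params(row))
        except ValidationError as err:
            raise ValidationError(f"region {row['region']!r}: {err}") from err
    return out


def write_region_table(params: Iterable[RegionParameters], path: Union[str, Path]) -> None:
    """Write parameters back to the CSV dialect :func:`load_region_table` reads.

    Full-precision round trip: values survive write → read unchanged.
    """
    rows = []
    for p in params:
        rows.append({
            "region": p.region_name,
            "incidence": p.incidence_rate,
            "prev": p.prevalence_ratio.point,
            "prev_lo": p.prevalence_ratio.ui_low,
            "prev_hi": p.prevalence_ratio.ui_high,
            "ibd_death": p.ibd_death_rate.point,
            "ibd_death_lo": p.ibd_death_rate.ui_low,
            "ibd_death_hi": p.ibd_death_rate.ui_high,
            "bg_death": p.background_death_rate.point,
            "bg_death_lo": p.background_death_rate.ui_low,
            "bg_death_hi": p.background_death_rate.ui_high,
            "initial_cases": p.initial_prevalent_cases,
            "start_year": p.start_year,
        })
    # shortest round-tripping decimal repr so write -> read is lossless
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


def load_builtin_table() -> list[RegionParameters]:
    """The packaged 2017 Asian-region parameter table (six regions)."""
    from importlib.resources import files

    return load_region_table(files("ibdforecast.data") / "asia_ibd_2017.csv")


def derive_initial_state(p: RegionParameters) -> CompartmentState:
    """Back-derive the start-year compartment state from printed quantities.

    total = cases / prevalence_ratio × 100,000, so the implied population is
    internally consistent with the printed prevalence.  A disease-free region
    (zero cases) carries no population information and is rejected; supply an
    explicit population and build the state directly in that case.
    """
    if p.initial_prevalent_cases <= 0:
        raise ValidationError(
            f"region {p.region_name!r}: cannot back-derive population from zero "
            "prevalent cases; construct CompartmentState with an explicit population"
        )
    if p.prevalence_ratio.point <= 0:
        raise ZeroDivisionError(
            f"region {p.region_name!r}: prevalence ratio is zero with "
            f"{p.initial_prevalent_cases} prevalent cases"
        )
    total = p.initial_prevalent_cases / p.prevalence_ratio.point * PER_100K
    return CompartmentState(
        year=float(p.start_year),
        healthy=total - p.initial_prevalent_cases,
        ibd=p.initial_prevalent_cases,
        dead_cum=0.0,
    )


def to_model_rates(
    p: RegionParameters,
    which: Literal["point", "ui_low", "ui_high"] = "point",
    birth_inflow: Union[float, str] = STATIONARY_HEALTHY,
) -> ModelRates:
    """Convert printed per-100,000 rates to per-capita annual hazards.

    The printed IBD death rate is deaths per 100,000 *total* population; the
    model needs a hazard per patient, so it is divided by the prevalence
    ratio (deaths among patients / patients), with both taken at the same
    ``which`` bound.  Incidence carries no printed interval and is used as-is.
    """
    prev = p.prevalence_ratio.bound(which)
    ibd_death = p.ibd_death_rate.bound(which)
    if ibd_death == 0.0:
        mu = 0.0
    else:
        if prev <= 0:
            raise ValidationError(
                f"region {p.region_name!r}: prevalence bound {which} is zero; "
                "per-patient mortality undefined"
            )
        mu = ibd_death / prev
    return ModelRates(
        lambda_inc=p.incidence_rate / PER_100K,
        mu_ibd=mu,
        d_background=p.background_death_rate.bound(which) / PER_100K,
        birth_inflow=birth_inflow,
    )
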