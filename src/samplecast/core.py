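"""Hospital-based sample-availability forecasting.

Given a population size, a disease prevalence, the number of hospitals the
cases are spread over, an attrition stratification, and the daily hours during
which an out-patients department (OPD) is accessible to the research team,
this module predicts how many study-eligible patients a single hospital yields
per year, how long sampling will take to reach a target sample size, and
simulates realistic day-by-day arrival fluctuation.

The deterministic chain runs

    S  = n * Pr / Pc                 annual diseased individuals in the population
    U  = S / X                       uniform split over X hospitals
    S' = U / X'                      equal split over X' attrition strata
                                     (did not seek care, seen elsewhere,
                                     misdiagnosed, death/remission, unknown);
                                     exactly one stratum reaches the researcher
    A  = n * (Pr/Pc) * (1/X) * (1/X')   closed form of the same quantity
    R  = A * h * dM * dY / (Yd * Hd)    time refinement: h sampling hours/day,
                                        dM working days/month, dY months/year,
                                        Yd days/year, Hd hours/day
    P  = (R / A) * (Pc / 100)           availability probability

with defaults X=100 hospitals, X'=5 strata, Yd=365, Hd=24, dM=27, dY=12.
Reported patient counts are floors of the continuous values; the count before
the five-way stratification ("WST", without stratification) is floor(R * X').

The stochastic layer models OPD arrivals as a homogeneous Poisson process per
working day (Sundays excluded — OPDs are closed), with the daily intensity
R / (dM * dY) chosen so the simulated annual mean matches the deterministic R.

Sections below follow the order the method runs: configuration & errors,
domain types, the availability chain, the OPD calendar simulator, then the
fixtures / report writers / CLI.
"""

from __future__ import annotations

import argparse
import datetime as _dt
import json
import logging
import math
import sys
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "UndefinedProbabilityError",
    "UnreachableTargetError",
    "TimeModel",
    "Scenario",
    "AvailabilityResult",
    "annual_cases",
    "distribute_to_hospitals",
    "stratify",
    "per_hospital_availability",
    "refine",
    "availability_probability",
    "evaluate_scenario",
    "hour_sweep",
    "SamplingCalendar",
    "DailySeries",
    "AccrualEstimate",
    "SeriesSummary",
    "build_calendar",
    "daily_rate",
    "simulate_daily_arrivals",
    "time_to_target",
    "summarize_series",
    "daily_series_frame",
    "write_daily_series",
    "PaperFixture",
    "paper_fixtures",
    "RunConfig",
    "load_config",
    "write_report",
    "run_cli",
    "main",
]

# --------------------------------------------------------------------------
# Configuration & errors
# --------------------------------------------------------------------------

logger = logging.getLogger("samplecast")

#: Default number of hospitals the annual cases are spread over.
DEFAULT_HOSPITALS = 100
#: Default number of equal attrition strata; one stratum is available.
DEFAULT_STRATA = 5
#: Percentage base: prevalence is expressed against 100%.
DEFAULT_PCT_BASE = 100.0
#: Default seed used by the command-line interface when none is given.
CLI_DEFAULT_SEED = 1234

REPORT_COLUMNS = (
    "prevalence_pct",
    "hours",
    "S",
    "U",
    "S_prime",
    "A",
    "R",
    "predicted_wst",
    "predicted",
    "P",
)


class ValidationError(ValueError):
    """An input violated a precondition; the message names the field."""


class UndefinedProbabilityError(ArithmeticError):
    """Availability probability requested for a scenario with A = 0."""


class UnreachableTargetError(ArithmeticError):
    """Accrual target requested under a zero arrival rate."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeModel:
    """Calendar constants of the time-refinement step.

    Parameters
    ----------
    days_per_year
        Yd, calendar days per year (365).
    hours_per_day_total
        Hd, hours per day (24).
    working_days_per_month
        dM, OPD working days per month. 27 reproduces the published worked
        examples; see the methods note for the 26-vs-27 discrepancy.
    months_per_year
        dY, months per year (12).
    sampling_hours
        h, hours per day during which the team can access the OPD, in
        (0, Hd].
    """

    days_per_year: float = 365.0
    hours_per_day_total: float = 24.0
    working_days_per_month: float = 27.0
    months_per_year: float = 12.0
    sampling_hours: float = 1.0

    def __post_init__(self) -> None:
        _require(self.days_per_year > 0, f"days_per_year must be > 0 (got {self.days_per_year})")
        _require(
            self.hours_per_day_total > 0,
            f"hours_per_day_total must be > 0 (got {self.hours_per_day_total})",
        )
        _require(
            1 <= self.working_days_per_month <= 31,
            f"working_days_per_month must be in [1, 31] (got {self.working_days_per_month})",
        )
        _require(
            self.months_per_year >= 1,
            f"months_per_year must be >= 1 (got {self.months_per_year})",
        )
        _require(
            self.working_days_per_month * self.months_per_year <= self.days_per_year,
            "working_days_per_month * months_per_year must not exceed days_per_year "
            f"(got {self.working_days_per_month} * {self.months_per_year} > {self.days_per_year})",
        )
        _require(
            0 < self.sampling_hours <= self.hours_per_day_total,
            f"sampling_hours must be in (0, {self.hours_per_day_total}] (got {self.sampling_hours})",
        )

    @property
    def working_days_per_year(self) -> float:
        """dM * dY, the model's working days per year (324 by default)."""
        return self.working_days_per_month * self.months_per_year


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one availability-prediction problem."""

    population_size: float
    prevalence_pct: float
    hospital_count: int = DEFAULT_HOSPITALS
    strata_count: int = DEFAULT_STRATA
    pct_base: float = DEFAULT_PCT_BASE
    time_model: TimeModel = field(default_factory=TimeModel)

    def __post_init__(self) -> None:
        _require(
            self.population_size >= 0,
            f"population_size must be >= 0 (got {self.population_size})",
        )
        _require(self.pct_base > 0, f"pct_base must be > 0 (got {self.pct_base})")
        _require(
            0 <= self.prevalence_pct <= self.pct_base,
            f"prevalence_pct must be in [0, {self.pct_base}] (got {self.prevalence_pct})",
        )
        _require(
            self.hospital_count >= 1,
            f"hospital_count must be >= 1 (got {self.hospital_count})",
        )
        _require(
            self.strata_count >= 1,
            f"strata_count must be >= 1 (got {self.strata_count})",
        )
        if self.pct_base != 100:
            warnings.warn(
                "pct_base != 100 changes the meaning of the availability "
                "probability P, which carries a (pct_base/100) factor",
                UserWarning,
                stacklevel=2,
            )

    def with_hours(self, hours: float) -> "Scenario":
        """Copy of this scenario with a different daily sampling-hour value."""
        return replace(self, time_model=replace(self.time_model, sampling_hours=hours))


@dataclass(frozen=True)
class AvailabilityResult:
    """All intermediate quantities of one scenario evaluation.

    ``predicted`` and ``predicted_without_stratification`` are the floors of
    the continuous refined values; everything else is unrounded.
    """

    scenario: Scenario
    annual_cases: float  # S
    per_hospital: float  # U
    per_stratum: float  # S' == A
    refined: float  # R
    probability: float  # P
    predicted_without_stratification: int  # floor(R * strata), the "WST" count
    predicted: int  # floor(R)


# --------------------------------------------------------------------------
# Availability chain (deterministic core)
# --------------------------------------------------------------------------


def annual_cases(population_size: float, prevalence_pct: float, pct_base: float = DEFAULT_PCT_BASE) -> float:
    """Expected diseased individuals per year in the whole population.

    S = n * Pr / Pc, continuous (no rounding).
    """
    _require(population_size >= 0, f"population_size must be >= 0 (got {population_size})")
    _require(pct_base > 0, f"pct_base must be > 0 (got {pct_base})")
    _require(
        0 <= prevalence_pct <= pct_base,
        f"prevalence_pct must be in [0, {pct_base}] (got {prevalence_pct})",
    )
    return population_size * prevalence_pct / pct_base


def distribute_to_hospitals(annual: float, hospital_count: int) -> float:
    """Uniform split of the annual cases over the hospitals: U = S / X."""
    _require(hospital_count >= 1, f"hospital_count must be >= 1 (got {hospital_count})")
    return annual / hospital_count


def stratify(per_hospital: float, strata_count: int) -> float:
    """Equal split over the attrition strata: S' = U / X'.

    Cases are divided equally over the possible fates (did not seek care,
    seen elsewhere, misdiagnosed, death/remission before diagnosis, unknown);
    exactly one stratum is available for sampling, so S' is the per-hospital
    annual count the researcher can actually reach.
    """
    _require(strata_count >= 1, f"strata_count must be >= 1 (got {strata_count})")
    return per_hospital / strata_count


def per_hospital_availability(scenario: Scenario) -> float:
    """Closed form A = n * (Pr/Pc) * (1/X) * (1/X').

    Algebraically identical to chaining ``annual_cases``,
    ``distribute_to_hospitals`` and ``stratify``.
    """
    return (
        scenario.population_size
        * (scenario.prevalence_pct / scenario.pct_base)
        * (1.0 / scenario.hospital_count)
        * (1.0 / scenario.strata_count)
    )


def refine(availability: float, time_model: TimeModel) -> float:
    """Time-refined annual expectation R.

    R = A * h * dM * dY / (Yd * Hd). Computed as ``h`` times the one-hour
    value so that scaling in sampling hours is exactly linear.
    """
    _require(availability >= 0, f"availability must be >= 0 (got {availability})")
    per_unit_hour = (
        availability
        * time_model.working_days_per_month
        * time_model.months_per_year
        / (time_model.days_per_year * time_model.hours_per_day_total)
    )
    return time_model.sampling_hours * per_unit_hour


def availability_probability(refined: float, availability: float, pct_base: float = DEFAULT_PCT_BASE) -> float:
    """Availability probability P = (R / A) * (Pc / 100).

    With the default percentage base this is the accessible fraction of the
    year, h * dM * dY / (Yd * Hd), independent of population parameters.
    """
    if availability == 0:
        raise UndefinedProbabilityError(
            "availability probability is undefined when the per-hospital "
            "availability A is 0"
        )
    _require(availability > 0, f"availability must be > 0 (got {availability})")
    return (refined / availability) * (pct_base / 100.0)


def evaluate_scenario(scenario: Scenario) -> AvailabilityResult:
    """Run the full S -> U -> S' -> R -> P chain and report floored counts."""
    s = annual_cases(scenario.population_size, scenario.prevalence_pct, scenario.pct_base)
    u = distribute_to_hospitals(s, scenario.hospital_count)
    s_prime = stratify(u, scenario.strata_count)
    r = refine(s_prime, scenario.time_model)
    if s_prime > 0:
        p = availability_probability(r, s_prime, scenario.pct_base)
    else:
        p = float("nan")
    return AvailabilityResult(
        scenario=scenario,
        annual_cases=s,
        per_hospital=u,
        per_stratum=s_prime,
        refined=r,
        probability=p,
        predicted_without_stratification=math.floor(r * scenario.strata_count),
        predicted=math.floor(r),
    )


def hour_sweep(scenario: Scenario, hours: Sequence[float]) -> list[AvailabilityResult]:
    """Evaluate the scenario at each daily sampling-hour value.

    Returns one result per hour, in the given order. The continuous refined
    value is strictly increasing in hours.
    """
    _require(len(hours) > 0, "hours must be a non-empty list")
    hd = scenario.time_model.hours_per_day_total
    for h in hours:
        _require(0 < h <= hd, f"hours entries must be in (0, {hd}] (got {h})")
    return [evaluate_scenario(scenario.with_hours(h)) for h in hours]


# --------------------------------------------------------------------------
# OPD calendar & stochastic arrival simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingCalendar:
    """A span of calendar days with Sundays flagged as non-working.

    OPDs are closed on Sundays; every other day is a working day (no holiday
    support).
    """

    start_date: _dt.date
    duration_days: int
    working_day_flags: np.ndarray  # bool, one per day

    @property
    def dates(self) -> list[_dt.date]:
        return [self.start_date + _dt.timedelta(days=i) for i in range(self.duration_days)]

    @property
    def working_day_count(self) -> int:
        return int(self.working_day_flags.sum())


@dataclass(frozen=True)
class DailySeries:
    """Simulated per-calendar-day arrival counts over a sampling period."""

    calendar: SamplingCalendar
    counts: np.ndarray  # non-negative int, one per day
    seed: int


@dataclass(frozen=True)
class AccrualEstimate:
    """Expected sampling time to reach a target sample size."""

    target_n: int
    expected_days: float  # continuous working days
    expected_days_ceil: int
    expected_years: float  # target_n / R


@dataclass(frozen=True)
class SeriesSummary:
    """Totals and working-day statistics of a daily series."""

    total: int
    working_day_mean: float
    working_day_sd: float
    max_count: int


def build_calendar(start_date: _dt.date, duration_days: int) -> SamplingCalendar:
    """Build a sampling calendar of ``duration_days`` starting at ``start_date``.

    Sundays are non-working; everything else works. Deterministic.
    """
    _require(duration_days >= 1, f"duration_days must be >= 1 (got {duration_days})")
    if isinstance(start_date, str):
        start_date = _dt.date.fromisoformat(start_date)
    # date.weekday(): Monday=0 .. Sunday=6
    flags = np.array(
        [(start_date + _dt.timedelta(days=i)).weekday() != 6 for i in range(duration_days)],
        dtype=bool,
    )
    return SamplingCalendar(start_date=start_date, duration_days=duration_days, working_day_flags=flags)


def daily_rate(scenario: Scenario) -> float:
    """Expected arrivals per working day: R / (dM * dY).

    The annual refined expectation is spread uniformly over the model's
    dM * dY working days (324 by default), so a simulated 324-working-day
    year has mean total R.
    """
    result = evaluate_scenario(scenario)
    return result.refined / scenario.time_model.working_days_per_year


def simulate_daily_arrivals(scenario: Scenario, calendar: SamplingCalendar, seed: int) -> DailySeries:
    """Draw independent Poisson arrival counts for every working day.

    Counts are 0 on Sundays. Identical (scenario, calendar, seed) inputs give
    bit-identical series.
    """
    rate = daily_rate(scenario)
    rng = np.random.default_rng(seed)
    counts = np.zeros(calendar.duration_days, dtype=np.int64)
    working = calendar.working_day_flags
    counts[working] = rng.poisson(rate, int(working.sum()))
    return DailySeries(calendar=calendar, counts=counts, seed=seed)


def time_to_target(scenario: Scenario, target_n: int) -> AccrualEstimate:
    """Expected working days (and calendar years) to accrue ``target_n`` samples."""
    _require(target_n >= 1, f"target_n must be >= 1 (got {target_n})")
    rate = daily_rate(scenario)
    if rate == 0:
        raise UnreachableTargetError(
            f"target of {target_n} samples is unreachable: the expected arrival rate is 0/day"
        )
    expected_days = target_n / rate
    refined = evaluate_scenario(scenario).refined
    return AccrualEstimate(
        target_n=target_n,
        expected_days=expected_days,
        expected_days_ceil=math.ceil(expected_days),
        expected_years=target_n / refined,
    )


def summarize_series(series: DailySeries) -> SeriesSummary:
    """Total, working-day mean/SD (population SD), and maximum daily count."""
    _require(len(series.counts) > 0, "series must be non-empty")
    working_counts = series.counts[series.calendar.working_day_flags]
    if len(working_counts) == 0:
        mean = sd = 0.0
    else:
        mean = float(np.mean(working_counts))
        sd = float(np.std(working_counts))
    return SeriesSummary(
        total=int(series.counts.sum()),
        working_day_mean=mean,
        working_day_sd=sd,
        max_count=int(series.counts.max()),
    )


def daily_series_frame(series: DailySeries) -> pd.DataFrame:
    """Daily series as a DataFrame: date (ISO-8601), weekday, is_working_day, arrivals."""
    dates = series.calendar.dates
    return pd.DataFrame(
        {
            "date": [d.isoformat() for d in dates],
            "weekday": [d.strftime("%A") for d in dates],
            "is_working_day": series.calendar.working_day_flags,
            "arrivals": series.counts,
        }
    )


def write_daily_series(series: DailySeries, path: str | Path) -> Path:
    """Write the daily series to CSV; returns the path written."""
    path = Path(path)
    daily_series_frame(series).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Packaged worked-example fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PaperFixture:
    """A published worked scenario with its expected floored counts per hour.

    ``expected`` maps sampling hours to a dict with key ``predicted`` (the
    after-stratification count) and optionally ``predicted_wst`` (the count
    without the five-way split).
    """

    label: str
    scenario: Scenario
    expected: dict[float, dict[str, int]]


_SWEEP_POPULATION = 58_746_995
_JK_POPULATION = 12_300_000  # Jammu & Kashmir, 1.23 crore

_PREVALENCE_SWEEP = {
    3: (651, 130),
    9: (1955, 391),
    10: (2172, 434),
    12: (2607, 521),
    15: (3259, 651),
    17: (3693, 738),
}


def paper_fixtures() -> list[PaperFixture]:
    """The eight published worked scenarios with their printed integers.

    Six imaginary-disease prevalences (3–17%) on a 58,746,995 population,
    plus migraine (12%) and nephrolithiasis (15%) on 12,300,000.
    """
    out: list[PaperFixture] = []
    for pr, (wst, pred) in _PREVALENCE_SWEEP.items():
        expected: dict[float, dict[str, int]] = {1: {"predicted": pred, "predicted_wst": wst}}
        if pr == 3:
            # the hour-scaling narrative continues only for the 3% scenario
            expected[2] = {"predicted": 260}
            expected[3] = {"predicted": 391}
        out.append(
            PaperFixture(
                label=f"{pr}%",
                scenario=Scenario(population_size=_SWEEP_POPULATION, prevalence_pct=pr),
                expected=expected,
            )
        )
    out.append(
        PaperFixture(
            label="migraine",
            scenario=Scenario(population_size=_JK_POPULATION, prevalence_pct=12),
            expected={h: {"predicted": v} for h, v in zip((1, 2, 3, 4, 5), (109, 218, 327, 436, 545))},
        )
    )
    out.append(
        PaperFixture(
            label="kidney stone",
            scenario=Scenario(population_size=_JK_POPULATION, prevalence_pct=15),
            expected={3: {"predicted": 409}},
        )
    )
    return out


# --------------------------------------------------------------------------
# Configuration & report writing
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One CLI / config-file run: scenario parameters plus output options."""

    population: float = None  # type: ignore[assignment]  # required
    prevalence: float = None  # type: ignore[assignment]  # required
    hospitals: int = DEFAULT_HOSPITALS
    strata: int = DEFAULT_STRATA
    pct_base: float = DEFAULT_PCT_BASE
    dm: float = 27.0
    dy: float = 12.0
    yd: float = 365.0
    hd: float = 24.0
    hours: list[float] = field(default_factory=lambda: [1.0])
    target_n: Optional[int] = None
    simulate: bool = False
    seed: int = CLI_DEFAULT_SEED
    start_date: str = "2024-01-01"
    days: int = 365
    out: Optional[str] = None
    format: str = "csv"

    def __post_init__(self) -> None:
        _require(self.population is not None, "population is required")
        _require(self.prevalence is not None, "prevalence is required")
        _require(len(self.hours) > 0, "hours must be a non-empty list")
        _require(
            self.format in ("csv", "json"),
            f"format must be 'csv' or 'json' (got {self.format!r})",
        )
        # construct once to trigger full field validation
        self.scenario()

    def scenario(self, hours: Optional[float] = None) -> Scenario:
        tm = TimeModel(
            days_per_year=self.yd,
            hours_per_day_total=self.hd,
            working_days_per_month=self.dm,
            months_per_year=self.dy,
            sampling_hours=hours if hours is not None else self.hours[0],
        )
        return Scenario(
            population_size=self.population,
            prevalence_pct=self.prevalence,
            hospital_count=self.hospitals,
            strata_count=self.strata,
            pct_base=self.pct_base,
            time_model=tm,
        )


_CONFIG_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path, overrides: Optional[dict] = None) -> RunConfig:
    """Load a RunConfig from a YAML or TOML file.

    ``overrides`` (e.g. parsed CLI flags) take precedence over file values.
    Unknown keys and invalid values raise a ``ValidationError`` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    if path.suffix in (".toml",):
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must contain a mapping at the top level")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValidationError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write a RunConfig as YAML (round-trips through :func:`load_config`)."""
    path = Path(path)
    data = {f.name: getattr(config, f.name) for f in fields(config)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def _result_record(result: AvailabilityResult) -> dict:
    """One report row, values rounded to the presentation precision."""
    sc = result.scenario
    return {
        "prevalence_pct": sc.prevalence_pct,
        "hours": sc.time_model.sampling_hours,
        "S": round(result.annual_cases, 2),
        "U": round(result.per_hospital, 2),
        "S_prime": round(result.per_stratum, 2),
        "A": round(result.per_stratum, 2),
        "R": round(result.refined, 2),
        "predicted_wst": result.predicted_without_stratification,
        "predicted": result.predicted,
        "P": round(result.probability, 5),
    }


def write_report(results: Sequence[AvailabilityResult], format: str, path: str | Path) -> Path:
    """Write scenario results as CSV or JSON.

    CSV columns: prevalence_pct, hours, S, U, S_prime, A, R, predicted_wst,
    predicted, P — continuous values to 2 decimals, P to 5. JSON mirrors the
    same field names. Byte-deterministic for fixed inputs.
    """
    _require(len(results) > 0, "results must be non-empty")
    _require(format in ("csv", "json"), f"format must be 'csv' or 'json' (got {format!r})")
    path = Path(path)
    records = [_result_record(r) for r in results]
    if format == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
        return path
    lines = [",".join(REPORT_COLUMNS)]
    for rec in records:
        lines.append(
            ",".join(
                [
                    f"{rec['prevalence_pct']:g}",
                    f"{rec['hours']:g}",
                    f"{rec['S']:.2f}",
                    f"{rec['U']:.2f}",
                    f"{rec['S_prime']:.2f}",
                    f"{rec['A']:.2f}",
                    f"{rec['R']:.2f}",
                    str(rec["predicted_wst"]),
                    str(rec["predicted"]),
                    f"{rec['P']:.5f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# Command-line interface
# --------------------------------------------------------------------------


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="samplecast",
        description="Predict annual sample availability at a single hospital "
        "from population size, disease prevalence and OPD access hours.",
    )
    sub = parser.add_subparsers(dest="command", required=True)
    p = sub.add_parser("predict", help="evaluate a scenario (optionally a sampling-hour sweep)")
    p.add_argument("--config", type=str, default=None, help="YAML/TOML config file; flags override it")
    p.add_argument("--population", type=float, default=None, help="population size (persons)")
    p.add_argument("--prevalence", type=float, default=None, help="disease prevalence in percent")
    p.add_argument("--hospitals", type=int, default=None, help="number of hospitals (default 100)")
    p.add_argument("--strata", type=int, default=None, help="number of attrition strata (default 5)")
    p.add_argument("--pct-base", dest="pct_base", type=float, default=None, help="percentage base (default 100)")
    p.add_argument("--hours", type=float, nargs="+", default=None, help="sampling hours per day (one or more values)")
    p.add_argument("--dm", type=float, default=None, help="working days per month (default 27)")
    p.add_argument("--dy", type=float, default=None, help="months per year (default 12)")
    p.add_argument("--yd", type=float, default=None, help="days per year (default 365)")
    p.add_argument("--hd", type=float, default=None, help="hours per day (default 24)")
    p.add_argument("--target-n", dest="target_n", type=int, default=None, help="target sample size for accrual-time estimate")
    p.add_argument("--simulate", action="store_true", default=None, help="simulate day-by-day arrivals")
    p.add_argument("--seed", type=int, default=None, help=f"simulation seed (default {CLI_DEFAULT_SEED})")
    p.add_argument("--start-date", dest="start_date", type=str, default=None, help="simulation start date YYYY-MM-DD")
    p.add_argument("--days", type=int, default=None, help="simulation length in calendar days (default 365)")
    p.add_argument("--out", type=str, default=None, help="report output path")
    p.add_argument("--format", type=str, default=None, choices=("csv", "json"), help="report format")
    return parser


def _config_from_args(args: argparse.Namespace) -> RunConfig:
    overrides = {
        k: getattr(args, k)
        for k in _CONFIG_KEYS
        if hasattr(args, k) and getattr(args, k) is not None
    }
    if args.config:
        return load_config(args.config, overrides)
    return RunConfig(**overrides)


def _log_chain(result: AvailabilityResult) -> None:
    sc = result.scenario
    logger.info(
        "h=%g: S=%.2f annual cases -> U=%.2f per hospital -> S'=%.2f per stratum "
        "-> R=%.2f refined (P=%.5f); predicted %d before stratification, %d after",
        sc.time_model.sampling_hours,
        result.annual_cases,
        result.per_hospital,
        result.per_stratum,
        result.refined,
        result.probability,
        result.predicted_without_stratification,
        result.predicted,
    )


def run_cli(argv: Optional[Sequence[str]] = None) -> int:
    """Run the command-line interface; returns a process exit code."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO, format="%(message)s")
    try:
        config = _config_from_args(args)
        results = hour_sweep(config.scenario(), config.hours)
        for result in results:
            _log_chain(result)
        if config.target_n is not None:
            est = time_to_target(config.scenario(), config.target_n)
            logger.info(
                "target n=%d at %g h/day: %.1f working days (%d ceil), %.2f years",
                est.target_n,
                config.hours[0],
                est.expected_days,
                est.expected_days_ceil,
                est.expected_years,
            )
        if config.out:
            path = write_report(results, config.format, config.out)
            logger.info("report written to %s", path)
        else:
            header = ",".join(REPORT_COLUMNS)
            print(header)
            for result in results:
                rec = _result_record(result)
                print(",".join(f"{rec[c]:g}" if isinstance(rec[c], float) else str(rec[c]) for c in REPORT_COLUMNS))
        if config.simulate:
            calendar = build_calendar(_dt.date.fromisoformat(config.start_date), config.days)
            series = simulate_daily_arrivals(config.scenario(), calendar, config.seed)
            summary = summarize_series(series)
            if config.out:
                daily_path = Path(config.out).with_suffix("")
                daily_path = daily_path.parent / (daily_path.name + "_daily.csv")
            else:
                daily_path = Path("daily_series.csv")
            write_daily_series(series, daily_path)
            logger.info(
                "simulated %d days (seed %d): total %d arrivals, mean %.3f/working day, "
                "SD %.3f, max %d; series written to %s",
                config.days,
                config.seed,
                summary.total,
                summary.working_day_mean,
                summary.working_day_sd,
                summary.max_count,
                daily_path,
            )
        return 0
    except (ValidationError, UndefinedProbabilityError, UnreachableTargetError) as exc:
        print(f"samplecast: error: {exc}", file=sys.stderr)
        return 1
    except OSError as exc:
        print(f"samplecast: error: {exc}", file=sys.stderr)
        return 1


def main() -> None:  # console-script entry point
    sys.exit(run_cli(sys.argv[1:]))
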