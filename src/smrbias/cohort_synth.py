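"""Synthetic retrospective cohort and reference mortality table.

No individual-level data from the motivating migrant-cohort study are
available, so this module generates a cohort with the statistical structure
the SMR analysis assumes and calibrates it to the study's published
aggregates: roughly 3,000 men entering 1990–1999, followed to 2010-05-10,
accumulating ~44,000 person-years with 251 deaths, 80 of them from the
cause of interest (cardiovascular disease), and a cause-specific SMR of
0.82 against a reference population whose mortality is tabulated in
five-year age bands by calendar year.

The generative model is a Lexis-style piecewise-exponential survival model:
the all-cause death hazard is constant within each age-band x calendar-year
cell and equals the reference rate for that cell times a per-band cohort
multiplier; deaths are assigned to the cause of interest with an
age-band-specific probability; loss to follow-up is independent exponential
censoring.  Death times are drawn by inversion of the piecewise-exponential
survival function, so realized stratum counts converge to hazard x PY.

Randomness: a single integer master seed; sub-streams are derived with the
fixed offsets in ``_STREAM_OFFSETS`` (entry dates, entry ages, death times,
loss times, cause assignment), so identical parameters give byte-identical
cohorts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import DAYS_PER_YEAR, band_label, completed_age, split_follow_up
from .exceptions import (
    CalibrationError,
    ConfigurationError,
    GenerationError,
    InputError,
    ReferenceCoverageError,
)

__all__ = [
    "AgeDistribution",
    "RateModel",
    "CohortParams",
    "Individual",
    "CalibrationTargets",
    "ExpectedAggregates",
    "RateGrid",
    "default_rate_model",
    "default_params",
    "default_targets",
    "generate_reference",
    "generate_cohort",
    "calibrate_cohort",
    "expected_aggregates",
    "cohort_to_csv",
    "cohort_from_csv",
    "reference_to_csv",
    "reference_from_csv",
]

# Fixed offsets applied to the master seed, one per random sub-stream.
_STREAM_OFFSETS = {
    "entry_date": 11,
    "entry_age": 23,
    "death": 37,
    "loss": 51,
    "cause": 67,
}

REFERENCE_COLUMNS = [
    "age_group",
    "calendar_year",
    "cause_deaths",
    "all_cause_deaths",
    "midyear_population",
]

COHORT_COLUMNS = ["id", "birth_date", "entry_date", "exit_date", "status", "cause"]

STATUS_ALIVE = "alive_censored"
STATUS_DEAD = "dead"
STATUS_LOST = "lost"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    """One cohort member; ``cause_of_interest`` is defined only for deaths."""

    id: str
    birth_date: date
    entry_date: date
    exit_date: date
    status: str
    cause_of_interest: bool | None = None

    def __post_init__(self):
        if self.entry_date >= self.exit_date:
            raise InputError(
                f"individual {self.id}: exit {self.exit_date} not after entry {self.entry_date}"
            )
        if self.birth_date >= self.entry_date:
            raise InputError(
                f"individual {self.id}: birth {self.birth_date} not before entry"
            )
        if self.status not in (STATUS_ALIVE, STATUS_DEAD, STATUS_LOST):
            raise InputError(f"individual {self.id}: unknown status {self.status!r}")
        if self.status == STATUS_DEAD and self.cause_of_interest is None:
            raise InputError(f"individual {self.id}: dead without cause flag")
        if self.status != STATUS_DEAD and self.cause_of_interest is not None:
            raise InputError(f"individual {self.id}: cause flag set but not dead")

    @property
    def follow_up_years(self) -> float:
        return (self.exit_date.toordinal() - self.entry_date.toordinal()) / DAYS_PER_YEAR


@dataclass(frozen=True)
class AgeDistribution:
    """Parameterised age-at-entry distribution (``truncnorm`` or ``uniform``)."""

    name: str = "truncnorm"
    mean: float = 37.36
    sd: float = 19.0
    lower: float = 0.0
    upper: float = 85.0

    def __post_init__(self):
        if self.name not in ("truncnorm", "uniform"):
            raise ConfigurationError(f"unknown age distribution {self.name!r}")
        if not self.lower < self.upper:
            raise ConfigurationError("age distribution needs lower < upper")
        if self.name == "truncnorm" and self.sd <= 0:
            raise ConfigurationError("truncnorm sd must be positive")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "uniform":
            return rng.uniform(self.lower, self.upper, n)
        return self._frozen().rvs(size=n, random_state=rng)

    def quadrature(self, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Midpoint nodes and probability weights for numerical expectation."""
        edges = np.arange(self.lower, self.upper + step / 2, step)
        if edges[-1] < self.upper:
            edges = np.append(edges, self.upper)
        mids = 0.5 * (edges[:-1] + edges[1:])
        if self.name == "uniform":
            weights = np.diff(edges) / (self.upper - self.lower)
        else:
            cdf = self._frozen().cdf(edges)
            weights = np.diff(cdf)
            weights = weights / weights.sum()
        return mids, weights


@dataclass(frozen=True)
class RateModel:
    """Reference-population mortality model.

    All-cause rates follow a Gompertz–Makeham hazard in age with a mild
    exponential calendar decline; the cause-of-interest (CVD-analog) share
    of deaths rises with age along a logistic curve, emulating the strong
    age gradient of cardiovascular death certification.  The numeric
    defaults are the package's frozen study conditions: they reproduce the
    aggregate structure of the motivating cohort analysis (overall SMR near
    unity, cause-specific SMR 0.82, a little over half of all deaths and the
    large majority of cause deaths above age 70).
    """

    makeham: float = 2.540e-4
    gompertz_a: float = 3.175e-5
    gompertz_b: float = 0.092
    annual_decline: float = 0.010
    base_year: int = 1990
    cause_floor: float = 0.2523
    cause_ceiling: float = 0.5170
    cause_midpoint: float = 71.0
    cause_width: float = 7.0
    population_scale: float = 450_000.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.gompertz_a <= 0 or self.gompertz_b <= 0 or self.makeham < 0:
            raise ConfigurationError("hazard coefficients must be positive")
        if not 0.0 <= self.cause_floor <= self.cause_ceiling <= 0.98:
            raise ConfigurationError("cause share must satisfy 0 <= floor <= ceiling <= 0.98")

    def all_cause_rate(self, age: float, year: int) -> float:
        rate = (self.makeham + self.gompertz_a * math.exp(self.gompertz_b * age)) * math.exp(
            -self.annual_decline * (year - self.base_year)
        )
        return min(rate, 0.95)

    def cause_share(self, age: float) -> float:
        z = (age - self.cause_midpoint) / self.cause_width
        return self.cause_floor + (self.cause_ceiling - self.cause_floor) / (
            1.0 + math.exp(-z)
        )

    def cause_rate(self, age: float, year: int) -> float:
        return self.all_cause_rate(age, year) * self.cause_share(age)

    def midyear_population(self, age: float) -> float:
        # Roughly bell-shaped national age pyramid; the absolute level only
        # sets how granular the reference counts are, not any rate.
        return self.population_scale * math.exp(-(((age - 30.0) / 42.0) ** 2))


def default_rate_model() -> RateModel:
    return RateModel()


class CalibrationTargets(NamedTuple):
    """Aggregate calibration targets (cohort totals and the cause SMR)."""

    total_deaths: float
    cause_deaths: float
    person_years: float
    smr: float


def default_targets() -> CalibrationTargets:
    """The published aggregates of the motivating male migrant cohort."""
    return CalibrationTargets(
        total_deaths=251.0, cause_deaths=80.0, person_years=44_000.0, smr=0.82
    )


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic cohort.

    ``hazard_multipliers`` maps age-band lower bounds to the cohort's
    all-cause hazard relative to the reference rate (a float applies to all
    bands); ``cause_fraction_by_age`` maps band lower bounds to the
    probability that a death in that band is a cause-of-interest death.
    """

    n_individuals: int = 3014
    entry_start: date = date(1990, 1, 1)
    entry_end: date = date(1999, 12, 31)
    follow_up_end: date = date(2010, 5, 10)
    entry_age: AgeDistribution = field(default_factory=AgeDistribution)
    hazard_multipliers: Mapping[int, float] | float = 1.0
    cause_fraction_by_age: Mapping[int, float] = field(default_factory=dict)
    loss_rate: float = 0.00145
    seed: int = 0
    band_width: int = 5

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if not self.entry_start <= self.entry_end < self.follow_up_end:
            raise ConfigurationError("need entry_start <= entry_end < follow_up_end")
        if isinstance(self.hazard_multipliers, Mapping):
            bad = {k: v for k, v in self.hazard_multipliers.items() if v < 0}
        else:
            bad = {} if self.hazard_multipliers >= 0 else {"*": self.hazard_multipliers}
        if bad:
            raise ConfigurationError(f"negative hazard multipliers: {bad}")
        for k, v in self.cause_fraction_by_age.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"cause fraction for band {k} outside [0, 1]: {v}")
        if not 0.0 <= self.loss_rate < 1.0:
            raise ConfigurationError("loss_rate must be in [0, 1)")

    def multiplier(self, band: int) -> float:
        if isinstance(self.hazard_multipliers, Mapping):
            try:
                return self.hazard_multipliers[band]
            except KeyError:
                raise ConfigurationError(f"no hazard multiplier for age band {band}")
        return float(self.hazard_multipliers)

    def cause_fraction(self, band: int) -> float:
        try:
            return self.cause_fraction_by_age[band]
        except KeyError:
            raise ConfigurationError(f"no cause fraction for age band {band}")

    def scaled(self, multiplier_scale: float = 1.0, cause_scale: float = 1.0) -> "CohortParams":
        """Return params with all multipliers / cause fractions rescaled."""
        if isinstance(self.hazard_multipliers, Mapping):
            mults: Mapping[int, float] | float = {
                k: v * multiplier_scale for k, v in self.hazard_multipliers.items()
            }
        else:
            mults = self.hazard_multipliers * multiplier_scale
        fracs = {k: v * cause_scale for k, v in self.cause_fraction_by_age.items()}
        for k, v in fracs.items():
            if v > 1.0:
                raise CalibrationError(
                    f"cause fraction for band {k} exceeds 1 after scaling ({v:.3f})"
                )
        return replace(self, hazard_multipliers=mults, cause_fraction_by_age=fracs)


def default_cause_fractions(
    model: RateModel | None = None,
    scale: float = 0.847,
    band_width: int = 5,
    max_age: int = 110,
) -> dict[int, float]:
    """Cohort cause-of-death fractions per band: the reference cause-share
    curve scaled down so the cohort's cause-specific SMR sits below its
    all-cause SMR (the protective-effect pattern of the motivating study)."""
    model = model or default_rate_model()
    lowers = range(0, max_age, band_width)
    return {
        lo: min(1.0, scale * model.cause_share(lo + (band_width - 1) / 2.0))
        for lo in lowers
    }


def default_params(seed: int = 0) -> CohortParams:
    """The frozen default study conditions (pre-calibrated; see docs)."""
    return CohortParams(
        n_individuals=3014,
        hazard_multipliers=0.9668,
        cause_fraction_by_age=default_cause_fractions(),
        seed=seed,
    )


# --------------------------------------------------------------------------
# Reference table
# --------------------------------------------------------------------------


def generate_reference(
    years: Sequence[int] | range = range(1990, 2011),
    band_lowers: Sequence[int] = tuple(range(0, 110, 5)),
    model: RateModel | None = None,
    seed: int = 0,
    band_width: int = 5,
) -> pd.DataFrame:
    """Deterministic reference mortality table, one row per band x year.

    ``cause_deaths``/``all_cause_deaths`` are real-valued expected counts
    (rate x midyear population); with ``model.noise_sd > 0`` a seeded
    mean-one lognormal perturbation is applied to the all-cause level.
    """
    years = list(years)
    band_lowers = sorted(band_lowers)
    if not years or not band_lowers:
        raise ConfigurationError("empty year range or age-band list")
    model = model or default_rate_model()
    rng = np.random.default_rng(seed)
    rows = []
    for lo in band_lowers:
        mid = lo + (band_width - 1) / 2.0
        for year in years:
            pop = model.midyear_population(mid)
            rate = model.all_cause_rate(mid, year)
            if model.noise_sd > 0:
                rate *= rng.lognormal(-model.noise_sd**2 / 2.0, model.noise_sd)
            share = min(model.cause_share(mid), 1.0)
            rows.append(
                {
                    "age_group": band_label(lo, band_width),
                    "calendar_year": year,
                    "cause_deaths": rate * share * pop,
                    "all_cause_deaths": rate * pop,
                    "midyear_population": pop,
                }
            )
    return pd.DataFrame(rows, columns=REFERENCE_COLUMNS)


class RateGrid:
    """Fast (band_lower, year) -> (all-cause rate, cause rate) lookup built
    from a reference table; raises :class:`ReferenceCoverageError` naming
    the missing stratum on a lookup outside coverage."""

    def __init__(self, reference: pd.DataFrame, band_width: int = 5):
        self.band_width = band_width
        self._rates: dict[tuple[int, int], tuple[float, float]] = {}
        from .bands import parse_band_lower

        for row in reference.itertuples(index=False):
            lo = parse_band_lower(row.age_group)
            pop = float(row.midyear_population)
            if pop <= 0:
                raise InputError(f"non-positive midyear population in band {row.age_group}")
            self._rates[(lo, int(row.calendar_year))] = (
                float(row.all_cause_deaths) / pop,
                float(row.cause_deaths) / pop,
            )

    def rates(self, band: int, year: int) -> tuple[float, float]:
        try:
            return self._rates[(band, year)]
        except KeyError:
            raise ReferenceCoverageError(band_label(band, self.band_width), year) from None

    def all_cause(self, band: int, year: int) -> float:
        return self.rates(band, year)[0]

    def cause(self, band: int, year: int) -> float:
        return self.rates(band, year)[1]


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


def generate_cohort(params: CohortParams, reference: pd.DataFrame) -> list[Individual]:
    """Draw a cohort from the piecewise-exponential model.

    Death times are sampled by inversion: a unit-exponential threshold is
    compared with the cumulative hazard accumulated over the individual's
    band x year fragments.  Loss to follow-up is an independent exponential
    clock; the administrative end of follow-up censors everyone else.
    """
    grid = RateGrid(reference, params.band_width)
    n = params.n_individuals
    rngs = {
        name: np.random.default_rng(params.seed + off) for name, off in _STREAM_OFFSETS.items()
    }

    start_ord = params.entry_start.toordinal()
    end_entry_ord = params.entry_end.toordinal()
    admin_ord = params.follow_up_end.toordinal()

    entry_ords = rngs["entry_date"].integers(start_ord, end_entry_ord + 1, n)
    ages = params.entry_age.sample(rngs["entry_age"], n)
    thresholds = rngs["death"].exponential(1.0, n)
    if params.loss_rate > 0:
        loss_days = rngs["loss"].exponential(DAYS_PER_YEAR / params.loss_rate, n)
    else:
        loss_days = np.full(n, np.inf)
    cause_u = rngs["cause"].uniform(0.0, 1.0, n)

    individuals: list[Individual] = []
    for i in range(n):
        entry = date.fromordinal(int(entry_ords[i]))
        birth = entry - timedelta(days=max(1, round(float(ages[i]) * DAYS_PER_YEAR)))
        try:
            segments = split_follow_up(birth, entry, params.follow_up_end, params.band_width)
        except ConfigurationError as err:
            raise GenerationError(f"individual {i}: {err}") from err

        death_t: float | None = None
        cum = 0.0
        for seg_start, seg_end, band, year in segments:
            try:
                rate = grid.all_cause(band, year) * params.multiplier(band)
            except ReferenceCoverageError as err:
                raise GenerationError(
                    f"individual {i} (born {birth}) reached uncovered stratum: {err}"
                ) from err
            h_day = rate / DAYS_PER_YEAR
            seg_hazard = h_day * (seg_end - seg_start)
            if cum + seg_hazard >= thresholds[i] and h_day > 0:
                death_t = seg_start + (thresholds[i] - cum) / h_day
                break
            cum += seg_hazard

        loss_t = float(entry_ords[i]) + float(loss_days[i])
        candidates = [(float(admin_ord), STATUS_ALIVE)]
        if death_t is not None:
            candidates.append((death_t, STATUS_DEAD))
        if math.isfinite(loss_t):
            candidates.append((loss_t, STATUS_LOST))
        exit_f, status = min(candidates, key=lambda c: c[0])
        exit_ord = int(min(max(round(exit_f), entry_ords[i] + 1), admin_ord))
        exit_date = date.fromordinal(exit_ord)

        cause: bool | None = None
        if status == STATUS_DEAD:
            band_at_exit = (completed_age(birth, exit_date) // params.band_width) * params.band_width
            cause = bool(cause_u[i] < params.cause_fraction(band_at_exit))

        individuals.append(
            Individual(
                id=f"S{i:06d}",
                birth_date=birth,
                entry_date=entry,
                exit_date=exit_date,
                status=status,
                cause_of_interest=cause,
            )
        )
    return individuals


# --------------------------------------------------------------------------
# Analytic expectations and calibration
# --------------------------------------------------------------------------


@dataclass
class ExpectedAggregates:
    """Analytic (numerically integrated) expectations under the model."""

    person_years: float
    deaths: float
    cause_deaths: float
    expected_cause: float  # reference cause rate x E[PY], summed over strata
    expected_all: float
    py_by_stratum: dict[tuple[int, int], float] | None = None
    deaths_by_stratum: dict[tuple[int, int], float] | None = None

    @property
    def smr_cause(self) -> float:
        return self.cause_deaths / self.expected_cause

    @property
    def smr_all(self) -> float:
        return self.deaths / self.expected_all


def expected_aggregates(
    params: CohortParams,
    reference: pd.DataFrame,
    age_step: float = 1.0,
    entry_intervals: int = 40,
    per_stratum: bool = False,
) -> ExpectedAggregates:
    """Expected cohort aggregates by quadrature over the entry distribution.

    Entry dates are integrated by midpoints of ``entry_intervals`` equal
    slices of the entry window; entry age by midpoint quadrature of the age
    distribution.  Conditional on an entry node the model is piecewise
    exponential, so person-years and death expectations per fragment are
    closed-form; no sampling is involved.
    """
    grid = RateGrid(reference, params.band_width)
    ages, age_w = params.entry_age.quadrature(age_step)
    start_ord = params.entry_start.toordinal()
    window = params.entry_end.toordinal() + 1 - start_ord
    entry_nodes = [
        int(round(start_ord + window * (k + 0.5) / entry_intervals))
        for k in range(entry_intervals)
    ]
    entry_w = 1.0 / entry_intervals
    loss_day = params.loss_rate / DAYS_PER_YEAR

    py = deaths = cause = exp_cause = exp_all = 0.0
    py_strata: dict[tuple[int, int], float] = {}
    death_strata: dict[tuple[int, int], float] = {}

    for entry_ord in entry_nodes:
        entry = date.fromordinal(entry_ord)
        for a0, w_age in zip(ages, age_w):
            weight = entry_w * float(w_age)
            if weight == 0.0:
                continue
            birth = entry - timedelta(days=max(1, round(float(a0) * DAYS_PER_YEAR)))
            survival = 1.0
            for seg_start, seg_end, band, year in split_follow_up(
                birth, entry, params.follow_up_end, params.band_width
            ):
                all_rate, cause_rate = grid.rates(band, year)
                h_death = all_rate * params.multiplier(band) / DAYS_PER_YEAR
                h_total = h_death + loss_day
                length = seg_end - seg_start
                if h_total > 0:
                    q = -math.expm1(-h_total * length)
                    py_days = survival * q / h_total
                    d_seg = survival * q * (h_death / h_total)
                else:
                    py_days = survival * length
                    d_seg = 0.0
                py_years = py_days / DAYS_PER_YEAR
                py += weight * py_years
                deaths += weight * d_seg
                cause += weight * d_seg * params.cause_fraction(band)
                exp_cause += weight * py_years * cause_rate
                exp_all += weight * py_years * all_rate
                if per_stratum:
                    key = (band, year)
                    py_strata[key] = py_strata.get(key, 0.0) + weight * py_years
                    death_strata[key] = death_strata.get(key, 0.0) + weight * d_seg
                survival *= math.exp(-h_total * length)

    n = params.n_individuals
    return ExpectedAggregates(
        person_years=n * py,
        deaths=n * deaths,
        cause_deaths=n * cause,
        expected_cause=n * exp_cause,
        expected_all=n * exp_all,
        py_by_stratum={k: n * v for k, v in py_strata.items()} if per_stratum else None,
        deaths_by_stratum={k: n * v for k, v in death_strata.items()} if per_stratum else None,
    )


def calibrate_cohort(
    targets: CalibrationTargets,
    base: CohortParams,
    reference: pd.DataFrame,
    tol: float = 0.02,
    max_iter: int = 30,
    age_step: float = 1.0,
    entry_intervals: int = 40,
) -> CohortParams:
    """Iterative proportional calibration of the cohort parameters.

    Per iteration: scale ``n_individuals`` to the person-years target, then
    the hazard multipliers to the total-death target, then the cause
    fractions to the cause-death target (the SMR depends on the ratio of
    cause deaths to reference-expected cause deaths, so decoupling the two
    scalings stabilises the iteration).  Expectations are analytic, hence
    the procedure is deterministic.  The SMR residual has no knob of its
    own — it is met when the reference table's cause rates are consistent
    with the targets (true for the defaults) and reported as a residual
    otherwise.
    """
    if min(targets) <= 0:
        raise ConfigurationError("calibration targets must be positive")
    if not 0.0 < tol < 0.5:
        raise ConfigurationError("tol must be in (0, 0.5)")

    params = base
    residuals: dict[str, float] = {}
    for _ in range(max_iter):
        agg = expected_aggregates(
            params, reference, age_step=age_step, entry_intervals=entry_intervals
        )
        if agg.deaths <= 0 or agg.cause_deaths <= 0:
            raise CalibrationError(
                "expected deaths vanish under the base parameters; cannot scale",
                {"deaths": float("inf")},
            )
        residuals = {
            "person_years": agg.person_years / targets.person_years - 1.0,
            "total_deaths": agg.deaths / targets.total_deaths - 1.0,
            "cause_deaths": agg.cause_deaths / targets.cause_deaths - 1.0,
            "smr": targets.cause_deaths / agg.expected_cause / targets.smr - 1.0,
        }
        n_new = max(1, round(params.n_individuals * targets.person_years / agg.person_years))
        mult_scale = targets.total_deaths / agg.deaths
        cause_scale = targets.cause_deaths / agg.cause_deaths
        # converged when the proportional update is a no-op (n is integer, so
        # the PY residual bottoms out at half-an-individual resolution)
        if n_new == params.n_individuals and abs(mult_scale - 1) < 1e-6 and abs(cause_scale - 1) < 1e-6:
            break
        params = replace(params, n_individuals=n_new).scaled(
            multiplier_scale=mult_scale, cause_scale=cause_scale
        )
    else:
        raise CalibrationError("calibration did not converge", residuals)

    if any(abs(r) > tol for r in residuals.values()):
        raise CalibrationError(
            "calibration converged but residuals exceed tolerance "
            "(is the reference table consistent with the SMR target?)",
            {k: round(v, 5) for k, v in residuals.items()},
        )
    return params


# --------------------------------------------------------------------------
# CSV import/export
# --------------------------------------------------------------------------


def reference_to_csv(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, index=False, columns=REFERENCE_COLUMNS)


def reference_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"reference CSV missing columns: {sorted(missing)}")
    return df[REFERENCE_COLUMNS]


def cohort_to_csv(cohort: Iterable[Individual], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for ind in cohort:
            cause = "" if ind.cause_of_interest is None else int(ind.cause_of_interest)
            writer.writerow(
                [
                    ind.id,
                    ind.birth_date.isoformat(),
                    ind.entry_date.isoformat(),
                    ind.exit_date.isoformat(),
                    ind.status,
                    cause,
                ]
            )


def cohort_from_csv(path) -> list[Individual]:
    individuals = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"cohort CSV missing columns: {sorted(missing)}")
        for row in reader:
            cause_raw = row["cause"].strip()
            individuals.append(
                Individual(
                    id=row["id"],
                    birth_date=date.fromisoformat(row["birth_date"]),
                    entry_date=date.fromisoformat(row["entry_date"]),
                    exit_date=date.fromisoformat(row["exit_date"]),
                    status=row["status"],
                    cause_of_interest=None if cause_raw == "" else bool(int(cause_raw)),
                )
            )
    return individuals
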