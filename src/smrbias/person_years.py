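"""Lexis stratification: accumulate each individual's time at risk into
age-band x calendar-year strata and tabulate observed deaths per stratum.

Each follow-up interval ``[entry, exit)`` is split at every birthday and
every January 1; a fragment contributes its day count / 365.25 to its
stratum.  Day counts are summed as integers per stratum and divided once,
so total stratified person-years equal total individual follow-up exactly
(up to one float division).  A death is counted in the stratum of the exit
date (age at exit, year of exit).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import pandas as pd

from .bands import (
    DAYS_PER_YEAR,
    band_label,
    band_lower,
    completed_age,
    parse_band_lower,
    split_follow_up,
)
from .cohort_synth import STATUS_DEAD, Individual
from .exceptions import InputError

__all__ = [
    "accumulate_person_years",
    "tabulate_deaths",
    "build_stratum_table",
    "coarsen_bands",
    "STRATUM_COLUMNS",
]

STRATUM_COLUMNS = [
    "age_group",
    "calendar_year",
    "person_years",
    "cause_deaths",
    "all_cause_deaths",
]


def _sorted_frame(rows: dict, columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"age_group": band_label(b, w), "calendar_year": y, **vals}
         for (b, y, w), vals in rows.items()],
        columns=columns,
    )
    if df.empty:
        return pd.DataFrame(columns=columns)
    df["_lo"] = df["age_group"].map(parse_band_lower)
    df = df.sort_values(["_lo", "calendar_year"]).drop(columns="_lo")
    return df.reset_index(drop=True)


def accumulate_person_years(
    cohort: Iterable[Individual], age_band_width: int = 5
) -> pd.DataFrame:
    """Stratified person-years table (columns age_group, calendar_year,
    person_years), empty cohort giving an empty table."""
    day_totals: dict[tuple[int, int, int], int] = defaultdict(int)
    for ind in cohort:
        if ind.exit_date <= ind.entry_date:
            raise InputError(f"individual {ind.id}: exit not after entry")
        for start, end, band, year in split_follow_up(
            ind.birth_date, ind.entry_date, ind.exit_date, age_band_width
        ):
            day_totals[(band, year, age_band_width)] += end - start
    rows = {
        key: {"person_years": days / DAYS_PER_YEAR} for key, days in day_totals.items()
    }
    return _sorted_frame(rows, ["age_group", "calendar_year", "person_years"])


def tabulate_deaths(cohort: Iterable[Individual], age_band_width: int = 5) -> pd.DataFrame:
    """Death counts per stratum (cause_deaths, all_cause_deaths columns)."""
    counts: dict[tuple[int, int, int], dict] = defaultdict(
        lambda: {"cause_deaths": 0, "all_cause_deaths": 0}
    )
    for ind in cohort:
        if ind.status != STATUS_DEAD:
            continue
        if ind.cause_of_interest is None:
            raise InputError(f"individual {ind.id}: dead without cause flag")
        band = band_lower(completed_age(ind.birth_date, ind.exit_date), age_band_width)
        cell = counts[(band, ind.exit_date.year, age_band_width)]
        cell["all_cause_deaths"] += 1
        if ind.cause_of_interest:
            cell["cause_deaths"] += 1
    return _sorted_frame(
        counts, ["age_group", "calendar_year", "cause_deaths", "all_cause_deaths"]
    )


def build_stratum_table(cohort: Iterable[Individual], age_band_width: int = 5) -> pd.DataFrame:
    """Full stratum table: person-years and death counts, outer-joined with
    zero fill (a death stratum always carries person-years, but not vice
    versa)."""
    cohort = list(cohort)
    py = accumulate_person_years(cohort, age_band_width)
    deaths = tabulate_deaths(cohort, age_band_width)
    if py.empty:
        return pd.DataFrame(columns=STRATUM_COLUMNS)
    merged = py.merge(deaths, on=["age_group", "calendar_year"], how="outer")
    merged[["person_years", "cause_deaths", "all_cause_deaths"]] = merged[
        ["person_years", "cause_deaths", "all_cause_deaths"]
    ].fillna(0.0)
    merged["_lo"] = merged["age_group"].map(parse_band_lower)
    merged = merged.sort_values(["_lo", "calendar_year"]).drop(columns="_lo")
    return merged[STRATUM_COLUMNS].reset_index(drop=True)


def coarsen_bands(table: pd.DataFrame, to_width: int) -> pd.DataFrame:
    """Re-aggregate a stratum table into wider bands (e.g. 1-year -> 5-year).

    Band lower bounds must align with ``to_width`` boundaries after integer
    division, which holds whenever the original width divides ``to_width``.
    """
    df = table.copy()
    df["_lo"] = df["age_group"].map(parse_band_lower).floordiv(to_width).mul(to_width)
    value_cols = [c for c in df.columns if c not in ("age_group", "calendar_year", "_lo")]
    out = (
        df.groupby(["_lo", "calendar_year"], as_index=False)[value_cols]
        .sum()
        .sort_values(["_lo", "calendar_year"])
    )
    out["age_group"] = out["_lo"].map(lambda lo: band_label(int(lo), to_width))
    return out[["age_group", "calendar_year", *value_cols]].reset_index(drop=True)
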