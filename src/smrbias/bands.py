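"""Age-band and calendar-time plumbing shared by the cohort generator and
the person-years engine.

Conventions (used consistently everywhere in the package):

* age is counted in completed years; band membership is evaluated at the
  start of each day, and bands are half-open ``[lower, lower + width)``;
* calendar years switch on January 1;
* one year is 365.25 days, so person-year totals are exact integer-day
  sums divided by a single constant;
* a February-29 birthday falls on March 1 in non-leap years.
"""

from __future__ import annotations

from datetime import date

from .exceptions import ConfigurationError

DAYS_PER_YEAR = 365.25


def band_lower(age: int, width: int = 5) -> int:
    """Lower bound of the age band containing ``age`` (completed years)."""
    if age < 0:
        raise ConfigurationError(f"negative age {age}")
    return (int(age) // width) * width


def band_label(lower: int, width: int = 5) -> str:
    """Human-readable band label, e.g. ``'70-74'`` for lower=70, width=5."""
    return f"{lower}-{lower + width - 1}"


def parse_band_lower(label: str) -> int:
    """Inverse of :func:`band_label`; accepts ``'70-74'``, ``'95+'`` or ``'70'``."""
    text = str(label).strip().rstrip("+")
    return int(text.split("-")[0])


def anniversary(birth: date, year: int) -> date:
    """The birthday of ``birth`` falling in calendar ``year``."""
    try:
        return date(year, birth.month, birth.day)
    except ValueError:  # Feb 29 in a non-leap year
        return date(year, 3, 1)


def completed_age(birth: date, on: date) -> int:
    """Age in completed years at the start of day ``on``."""
    age = on.year - birth.year
    if on < anniversary(birth, on.year):
        age -= 1
    return age


def next_birthday(birth: date, after: date) -> date:
    """First birthday strictly after ``after``."""
    candidate = anniversary(birth, after.year)
    if candidate <= after:
        candidate = anniversary(birth, after.year + 1)
    return candidate


def split_follow_up(
    birth: date, start: date, end: date, band_width: int = 5
) -> list[tuple[int, int, int, int]]:
    """Split the half-open interval ``[start, end)`` at every birthday and
    every January 1.

    Returns ``(start_ordinal, end_ordinal, band_lower, calendar_year)``
    fragments with constant age band and calendar year.  Splitting at every
    birthday (not only band-changing ones) is harmless — adjacent fragments
    that share a band simply accumulate into the same stratum.
    """
    if start >= end:
        return []
    pieces: list[tuple[int, int, int, int]] = []
    current = start
    while current < end:
        age = completed_age(birth, current)
        cut = min(next_birthday(birth, current), date(current.year + 1, 1, 1), end)
        pieces.append(
            (current.toordinal(), cut.toordinal(), band_lower(age, band_width), current.year)
        )
        current = cut
    return pieces
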