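"""Indirect standardization and SMR confidence intervals.

Expected deaths per stratum are the reference rate (deaths / midyear
population) times the cohort's person-years in that stratum; the SMR is
observed / expected with an exact (Garwood) Poisson confidence interval by
default.  Because misclassification-corrected counts are real-valued, the
exact interval is computed through its continuous gamma-quantile
generalization, which coincides with the classical chi-square form at
integer counts:

    lower = chi2_{alpha/2, 2k} / 2 / E = Gamma(k).ppf(alpha/2) / E
    upper = chi2_{1-alpha/2, 2k+2} / 2 / E = Gamma(k+1).ppf(1-alpha/2) / E
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd
from scipy import stats

from .exceptions import DomainError, InputError, ReferenceCoverageError

__all__ = ["SMREstimate", "expected_deaths", "expected_table", "compute_smr"]

CAUSE_OF_INTEREST = "cause_of_interest"
ALL_CAUSE = "all_cause"

_EXPECTED_COLUMN = {
    CAUSE_OF_INTEREST: "expected_cause_deaths",
    ALL_CAUSE: "expected_all_cause_deaths",
}


@dataclass(frozen=True)
class SMREstimate:
    """SMR point estimate with confidence interval.

    ``observed`` may be real-valued (corrected counts); ``point`` is always
    observed / expected and the interval always contains the point.
    """

    observed: float
    expected: float
    point: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str

    @property
    def significant(self) -> bool:
        """True when the CI excludes unity."""
        return self.ci_high < 1.0 or self.ci_low > 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def expected_deaths(
    reference: pd.DataFrame, py: pd.DataFrame, cause: str = CAUSE_OF_INTEREST
) -> pd.DataFrame:
    """Attach an expected-deaths column to a person-years stratum table.

    expected_s = (reference deaths_s / midyear population_s) x PY_s.
    Every cohort stratum with PY > 0 must be covered by the reference.
    """
    if cause not in _EXPECTED_COLUMN:
        raise InputError(f"unknown cause selector {cause!r}")
    deaths_col = "cause_deaths" if cause == CAUSE_OF_INTEREST else "all_cause_deaths"
    rates = {
        (row.age_group, int(row.calendar_year)): getattr(row, deaths_col)
        / row.midyear_population
        for row in reference.itertuples(index=False)
    }
    out = py.copy()
    expected = []
    for row in out.itertuples(index=False):
        key = (row.age_group, int(row.calendar_year))
        rate = rates.get(key)
        if rate is None:
            if row.person_years > 0:
                raise ReferenceCoverageError(*key)
            rate = 0.0
        expected.append(rate * row.person_years)
    out[_EXPECTED_COLUMN[cause]] = expected
    return out


def expected_table(reference: pd.DataFrame, py: pd.DataFrame) -> pd.DataFrame:
    """Stratum table with both cause-specific and all-cause expected deaths."""
    out = expected_deaths(reference, py, CAUSE_OF_INTEREST)
    return expected_deaths(reference, out, ALL_CAUSE)


def _garwood(observed: float, expected: float, alpha: float) -> tuple[float, float]:
    low = stats.gamma.ppf(alpha / 2.0, observed) / expected if observed > 0 else 0.0
    high = stats.gamma.ppf(1.0 - alpha / 2.0, observed + 1.0) / expected
    return float(low), float(high)


def _byar(observed: float, expected: float, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if observed > 0:
        low = observed * (1.0 - 1.0 / (9.0 * observed) - z / (3.0 * observed**0.5)) ** 3
    else:
        low = 0.0
    o1 = observed + 1.0
    high = o1 * (1.0 - 1.0 / (9.0 * o1) + z / (3.0 * o1**0.5)) ** 3
    return low / expected, high / expected


def compute_smr(
    observed_total: float,
    expected_total: float,
    alpha: float = 0.05,
    method: str = "garwood",
) -> SMREstimate:
    """SMR point estimate with an exact Poisson (Garwood) or Byar CI."""
    if expected_total <= 0:
        raise DomainError(f"expected deaths must be positive, got {expected_total}")
    if observed_total < 0:
        raise DomainError(f"observed deaths must be non-negative, got {observed_total}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if method == "garwood":
        low, high = _garwood(observed_total, expected_total, alpha)
    elif method == "byar":
        low, high = _byar(observed_total, expected_total, alpha)
    else:
        raise InputError(f"unknown CI method {method!r}")
    return SMREstimate(
        observed=float(observed_total),
        expected=float(expected_total),
        point=float(observed_total) / float(expected_total),
        ci_low=max(low, 0.0),
        ci_high=high,
        alpha=alpha,
        method=method,
    )
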