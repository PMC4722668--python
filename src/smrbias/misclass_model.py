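"""Misclassification algebra: forward contamination of true cause-specific
death counts by imperfect certification, and the inverse correction with
age-banded sensitivity/specificity.

Death certification is treated as a diagnostic test on each death: a true
cause-of-interest death is certified as such with sensitivity SE, a death
from any other cause is correctly excluded with specificity SP.  From the
2x2 table, for a stratum with D total deaths,

    observed  = SE * true + (1 - SP) * (D - true)              (forward)
    true      = (observed + SP * D - D) / (SE + SP - 1)        (inverse)

The inverse is undefined at SE + SP = 1 (an uninformative test).  Age
dependence is a binary step: one (SE, SP) pair below a cut-off age
(default 70) and one at/above it, applied per age band.

Because the inverse is linear in (observed, D) at fixed quality, summing
per-stratum corrections inside a quality band equals correcting the band
totals — the corrected-SMR routine exploits this, so single sparse strata
whose corrected count is slightly negative are absorbed linearly into the
totals rather than clamped (clamping each cell would destroy the algebraic
identity with the age-independent closed form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import parse_band_lower
from .exceptions import (
    ConfigurationError,
    DomainError,
    InputError,
    MisclassificationError,
    NonInvertibleError,
)
from .smr_engine import SMREstimate, compute_smr

__all__ = [
    "DiagnosticQuality",
    "FLAG_OK",
    "FLAG_CLAMPED_LOW",
    "FLAG_CLAMPED_HIGH",
    "contaminate_counts",
    "correct_counts",
    "correct_stratified",
    "corrected_totals",
    "true_smr",
    "rr_misclassified",
]

FLAG_OK = "ok"
FLAG_CLAMPED_LOW = "clamped_low"
FLAG_CLAMPED_HIGH = "clamped_high"


@dataclass(frozen=True)
class DiagnosticQuality:
    """Age-banded certification quality: (SE, SP) below and at/above a
    cut-off age.  The band containing the cut-off uses the 'above' values
    (the boundary is closed on the above side)."""

    se_below: float
    sp_below: float
    se_above: float
    sp_above: float
    cutoff_age: int = 70

    def __post_init__(self):
        for name in ("se_below", "sp_below", "se_above", "sp_above"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def uniform(cls, se: float, sp: float, cutoff_age: int = 70) -> "DiagnosticQuality":
        """Age-independent quality (identical values in both bands)."""
        return cls(se, sp, se, sp, cutoff_age)

    @classmethod
    def perfect(cls, cutoff_age: int = 70) -> "DiagnosticQuality":
        return cls.uniform(1.0, 1.0, cutoff_age)

    def pair(self, above: bool) -> tuple[float, float]:
        return (self.se_above, self.sp_above) if above else (self.se_below, self.sp_below)

    def is_above(self, band_lower_age: int, band_width: int) -> bool:
        """Which side of the cut-off a band lies on; the cut-off must sit
        on a band boundary."""
        if band_lower_age < self.cutoff_age < band_lower_age + band_width:
            raise ConfigurationError(
                f"cut-off age {self.cutoff_age} falls inside band "
                f"[{band_lower_age}, {band_lower_age + band_width})"
            )
        return band_lower_age >= self.cutoff_age

    def invertible(self, above: bool) -> bool:
        se, sp = self.pair(above)
        return abs(se + sp - 1.0) > 1e-12


def contaminate_counts(
    true_cause: float,
    all_cause: float,
    se: float,
    sp: float,
    mode: str = "expected",
    seed: int | np.random.Generator | None = None,
) -> float:
    """Forward operator: observed cause count under imperfect certification.

    ``expected`` mode is the deterministic mean; ``binomial`` mode draws
    Binomial(true, SE) + Binomial(D - true, 1 - SP) and needs integer
    counts.
    """
    if not 0.0 <= true_cause <= all_cause:
        raise InputError(f"need 0 <= true_cause <= all_cause, got {true_cause}, {all_cause}")
    if mode == "expected":
        return se * true_cause + (1.0 - sp) * (all_cause - true_cause)
    if mode == "binomial":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return float(
            rng.binomial(int(round(true_cause)), se)
            + rng.binomial(int(round(all_cause - true_cause)), 1.0 - sp)
        )
    raise InputError(f"unknown mode {mode!r}")


def correct_counts(
    observed_cause: float,
    all_cause: float,
    se: float,
    sp: float,
    clamp: bool = False,
) -> tuple[float, str]:
    """Inverse operator: unbiased cause count from an observed count.

    Returns ``(corrected, flag)``; out-of-range results are flagged and —
    only with ``clamp=True`` — clamped into ``[0, all_cause]``.
    """
    if not 0.0 <= observed_cause <= all_cause:
        raise InputError(
            f"need 0 <= observed_cause <= all_cause, got {observed_cause}, {all_cause}"
        )
    denom = se + sp - 1.0
    if abs(denom) < 1e-12:
        raise NonInvertibleError(f"SE + SP = 1 (SE={se}, SP={sp}): correction undefined")
    corrected = (observed_cause + sp * all_cause - all_cause) / denom
    flag = FLAG_OK
    if corrected < 0.0:
        flag = FLAG_CLAMPED_LOW
        if clamp:
            corrected = 0.0
    elif corrected > all_cause:
        flag = FLAG_CLAMPED_HIGH
        if clamp:
            corrected = all_cause
    return corrected, flag


def correct_stratified(
    counts: pd.DataFrame,
    quality: DiagnosticQuality,
    clamp: bool = False,
    band_width: int = 5,
    cause_col: str = "cause_deaths",
    total_col: str = "all_cause_deaths",
) -> pd.DataFrame:
    """Apply the inverse correction per stratum with the quality pair of
    the stratum's side of the cut-off.

    In strict mode (``clamp=False``) any out-of-range stratum raises
    :class:`MisclassificationError` listing the offending strata; in clamp
    mode cells are clamped and flagged so a grid scan survives degenerate
    cells.
    """
    out = counts.copy()
    corrected = []
    flags = []
    for row in out.itertuples(index=False):
        above = quality.is_above(parse_band_lower(row.age_group), band_width)
        se, sp = quality.pair(above)
        value, flag = correct_counts(
            getattr(row, cause_col), getattr(row, total_col), se, sp, clamp=clamp
        )
        corrected.append(value)
        flags.append(flag)
    out["corrected_cause_deaths"] = corrected
    out["flag"] = flags
    if not clamp:
        bad = [
            (row.age_group, int(row.calendar_year), flag)
            for row, flag in zip(out.itertuples(index=False), flags)
            if flag != FLAG_OK
        ]
        if bad:
            raise MisclassificationError("corrected counts out of range", bad)
    return out


def _band_totals(
    table: pd.DataFrame,
    quality: DiagnosticQuality,
    cause_col: str,
    total_col: str,
    band_width: int,
) -> tuple[float, float, float, float]:
    lowers = table["age_group"].map(parse_band_lower)
    above = np.array([quality.is_above(lo, band_width) for lo in lowers])
    cause = table[cause_col].to_numpy(float)
    total = table[total_col].to_numpy(float)
    return (
        float(cause[~above].sum()),
        float(total[~above].sum()),
        float(cause[above].sum()),
        float(total[above].sum()),
    )


def corrected_totals(
    table: pd.DataFrame,
    quality: DiagnosticQuality,
    cause_col: str = "cause_deaths",
    total_col: str = "all_cause_deaths",
    band_width: int = 5,
) -> tuple[float, float]:
    """(corrected cause total, all-cause total): the below- and above-cutoff
    band totals corrected with their quality pair and summed — identical to
    summing unclamped per-stratum corrections."""
    o_b, d_b, o_a, d_a = _band_totals(table, quality, cause_col, total_col, band_width)
    for above in (False, True):
        if not quality.invertible(above):
            se, sp = quality.pair(above)
            raise NonInvertibleError(f"SE + SP = 1 in {'above' if above else 'below'} band")
    corrected = 0.0
    for obs, tot, above in ((o_b, d_b, False), (o_a, d_a, True)):
        if tot > 0:
            se, sp = quality.pair(above)
            corrected += (obs + sp * tot - tot) / (se + sp - 1.0)
    return corrected, d_b + d_a


def true_smr(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    quality_cohort: DiagnosticQuality,
    quality_reference: DiagnosticQuality,
    alpha: float = 0.05,
    method: str = "garwood",
    clamp: bool = False,
    band_width: int = 5,
) -> SMREstimate:
    """Corrected ('true') SMR under age-banded, possibly differential
    misclassification.

    The numerator corrects the cohort's observed cause deaths (per-stratum
    all-cause deaths as D); the denominator applies the same inverse to the
    reference-expected cause deaths, with the expected all-cause deaths as
    D.  With perfect quality on both sides this reduces to the uncorrected
    SMR; with age-independent non-differential quality it equals the
    closed-form ratio (O + SP*D - D) / (E + SP*D_E - D_E), which does not
    involve SE.
    """
    corr_obs, d_total = corrected_totals(
        observed, quality_cohort, "cause_deaths", "all_cause_deaths", band_width
    )
    corr_exp, _ = corrected_totals(
        expected,
        quality_reference,
        "expected_cause_deaths",
        "expected_all_cause_deaths",
        band_width,
    )
    if corr_obs < 0.0 or corr_obs > d_total:
        if clamp:
            corr_obs = min(max(corr_obs, 0.0), d_total)
        else:
            raise DomainError(
                f"corrected observed count {corr_obs:.3f} outside [0, {d_total:.3f}]"
            )
    if corr_exp <= 0.0:
        raise DomainError(f"corrected expected count not positive: {corr_exp:.3f}")
    return compute_smr(corr_obs, corr_exp, alpha=alpha, method=method)


def rr_misclassified(
    p_exposed: float, p_unexposed: float, se: float, sp: float
) -> tuple[float, float]:
    """True and observed relative risk for two equal-size groups with equal
    total deaths whose true cause-of-death proportions are contaminated by
    the same (SE, SP).

    Under those symmetry assumptions the RR is the ratio of cause-of-death
    proportions, and the observed proportion is SE*p + (1-SP)*(1-p).
    """
    for name, p in (("p_exposed", p_exposed), ("p_unexposed", p_unexposed)):
        if not 0.0 <= p <= 1.0:
            raise InputError(f"{name} must be in [0, 1], got {p}")
    if p_unexposed == 0.0:
        raise DomainError("p_unexposed must be positive")
    rr_true = p_exposed / p_unexposed
    obs_exposed = contaminate_counts(p_exposed, 1.0, se, sp)
    obs_unexposed = contaminate_counts(p_unexposed, 1.0, se, sp)
    if obs_unexposed == 0.0:
        raise DomainError("observed unexposed proportion is zero")
    return rr_true, obs_exposed / obs_unexposed
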