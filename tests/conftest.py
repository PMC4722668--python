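"""Shared fixtures: the default reference table and calibrated cohort are
expensive (a few seconds), so they are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from smrbias import cohort_synth as cs
from smrbias.person_years import build_stratum_table
from smrbias.smr_engine import compute_smr, expected_table


@pytest.fixture(scope="session")
def reference():
    return cs.generate_reference()


@pytest.fixture(scope="session")
def calibrated_params(reference):
    return cs.calibrate_cohort(cs.default_targets(), cs.default_params(0), reference)


@pytest.fixture(scope="session")
def cohort(calibrated_params, reference):
    return cs.generate_cohort(calibrated_params, reference)


@pytest.fixture(scope="session")
def stratum_table(cohort, reference):
    """Observed strata joined with reference-expected deaths."""
    return expected_table(reference, build_stratum_table(cohort))


@pytest.fixture(scope="session")
def smr_observed(stratum_table):
    return compute_smr(
        stratum_table["cause_deaths"].sum(),
        stratum_table["expected_cause_deaths"].sum(),
    )


def random_stratum_tables(rng: np.random.Generator, n_strata: int = 12):
    """A consistent random (observed, expected) stratum-table pair whose
    cause fractions stay in [0.45, 0.65], so corrections with SP >= 0.7
    and SE >= 0.66 are regular (corrected counts inside [0, D]).  Returns
    one DataFrame carrying all four count columns."""
    import pandas as pd

    from smrbias.bands import band_label

    bands = rng.choice(np.arange(0, 105, 5), size=n_strata, replace=False)
    years = rng.integers(1990, 2011, size=n_strata)
    all_cause = rng.uniform(5.0, 60.0, size=n_strata)
    cause = all_cause * rng.uniform(0.45, 0.65, size=n_strata)
    exp_all = rng.uniform(5.0, 60.0, size=n_strata)
    exp_cause = exp_all * rng.uniform(0.45, 0.65, size=n_strata)
    return pd.DataFrame(
        {
            "age_group": [band_label(int(b)) for b in bands],
            "calendar_year": years,
            "person_years": rng.uniform(100.0, 5000.0, size=n_strata),
            "cause_deaths": cause,
            "all_cause_deaths": all_cause,
            "expected_cause_deaths": exp_cause,
            "expected_all_cause_deaths": exp_all,
        }
    )
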