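"""Cohort generator: reference-table structure, simulation consistency,
and aggregate calibration."""

from __future__ import annotations

import math
from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from smrbias import cohort_synth as cs
from smrbias.bands import DAYS_PER_YEAR, band_lower, completed_age, parse_band_lower
from smrbias.exceptions import CalibrationError, ConfigurationError, GenerationError


def small_params(**kwargs) -> cs.CohortParams:
    defaults = dict(
        n_individuals=300,
        entry_age=cs.AgeDistribution(mean=50.0, sd=15.0, lower=20.0, upper=80.0),
        hazard_multipliers=1.0,
        cause_fraction_by_age=cs.default_cause_fractions(),
        loss_rate=0.002,
        seed=7,
    )
    defaults.update(kwargs)
    return cs.CohortParams(**defaults)


class TestReference:
    def test_rates_monotone_in_age(self, reference):
        for _, year_block in reference.groupby("calendar_year"):
            block = year_block.assign(_lo=year_block.age_group.map(parse_band_lower))
            block = block.sort_values("_lo")
            all_rate = block.all_cause_deaths / block.midyear_population
            cause_rate = block.cause_deaths / block.midyear_population
            assert (np.diff(all_rate) >= -1e-12).all()
            assert (np.diff(cause_rate) >= -1e-12).all()

    def test_structure_and_determinism(self, reference):
        assert len(reference) == 22 * 21  # bands 0-4 .. 105-109, years 1990-2010
        assert (reference.cause_deaths <= reference.all_cause_deaths + 1e-12).all()
        assert (reference.midyear_population > 0).all()
        again = cs.generate_reference()
        pd.testing.assert_frame_equal(reference, again)

    def test_zero_cause_share_gives_zero_cause_deaths(self):
        model = cs.RateModel(cause_floor=0.0, cause_ceiling=0.0)
        ref = cs.generate_reference(years=range(1995, 1997), model=model)
        assert (ref.cause_deaths == 0.0).all()

    def test_empty_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            cs.generate_reference(years=[])
        with pytest.raises(ConfigurationError):
            cs.generate_reference(band_lowers=[])


class TestGenerateCohort:
    def test_deterministic_given_seed(self, reference):
        params = small_params(n_individuals=120)
        assert cs.generate_cohort(params, reference) == cs.generate_cohort(params, reference)

    def test_zero_multiplier_means_no_deaths(self, reference):
        params = small_params(hazard_multipliers=0.0)
        cohort = cs.generate_cohort(params, reference)
        assert all(ind.status != "dead" for ind in cohort)

    def test_invariants_hold(self, reference):
        params = small_params(n_individuals=200)
        for ind in cs.generate_cohort(params, reference):
            assert ind.birth_date < ind.entry_date < ind.exit_date
            assert ind.exit_date <= params.follow_up_end
            assert (ind.cause_of_interest is not None) == (ind.status == "dead")

    def test_death_count_matches_euler_oracle(self, reference):
        """Realized deaths lie within 4 SD of the death probability summed
        over individuals, computed by an independent coarse-grid numerical
        integration of the survival function."""
        params = small_params(n_individuals=1000, seed=11)
        cohort = cs.generate_cohort(params, reference)
        grid = cs.RateGrid(reference)
        loss_day = params.loss_rate / DAYS_PER_YEAR
        step = 15  # days
        probs = []
        for ind in cohort:
            survival, p_death = 1.0, 0.0
            day = ind.entry_date
            end = params.follow_up_end
            while day < end:
                nxt = min(day + timedelta(days=step), end)
                age_band = band_lower(completed_age(ind.birth_date, day))
                h_d = grid.all_cause(age_band, day.year) / DAYS_PER_YEAR
                h = h_d + loss_day
                dt = (nxt - day).days
                q = -math.expm1(-h * dt)
                p_death += survival * q * (h_d / h)
                survival *= 1.0 - q
                day = nxt
            probs.append(p_death)
        expected = sum(probs)
        sd = math.sqrt(sum(p * (1 - p) for p in probs))
        realized = sum(1 for ind in cohort if ind.status == "dead")
        assert abs(realized - expected) < 4.0 * sd

    def test_uncovered_stratum_raises_naming_it(self):
        ref = cs.generate_reference(band_lowers=tuple(range(0, 60, 5)))
        params = small_params(
            entry_age=cs.AgeDistribution(mean=70.0, sd=5.0, lower=60.0, upper=80.0)
        )
        with pytest.raises(GenerationError, match=r"\d+-\d+"):
            cs.generate_cohort(params, ref)

    def test_stratum_death_counts_chi_square_consistent(self, reference):
        """Over 100 replicates, pooled per-band death counts agree with the
        hazard x PY expectation (chi-square goodness of fit, alpha=0.001)."""
        from scipy import stats

        params = small_params(n_individuals=300, seed=0)
        agg = cs.expected_aggregates(params, reference, per_stratum=True)
        expected_by_band: dict[int, float] = {}
        for (band, _), d in agg.deaths_by_stratum.items():
            expected_by_band[band] = expected_by_band.get(band, 0.0) + d
        n_rep = 100
        observed_by_band = dict.fromkeys(expected_by_band, 0)
        for seed in range(1, n_rep + 1):
            for ind in cs.generate_cohort(replace(params, seed=seed), reference):
                if ind.status == "dead":
                    band = band_lower(completed_age(ind.birth_date, ind.exit_date))
                    observed_by_band[band] = observed_by_band.get(band, 0) + 1
        # pool sparse bands so every expected cell has >= 5 pooled counts
        cells = sorted(expected_by_band.items())
        obs, exp = [], []
        o_acc = e_acc = 0.0
        for band, e in cells:
            e_acc += n_rep * e
            o_acc += observed_by_band.get(band, 0)
            if e_acc >= 5.0:
                obs.append(o_acc)
                exp.append(e_acc)
                o_acc = e_acc = 0.0
        exp[-1] += e_acc
        obs[-1] += o_acc
        obs_arr, exp_arr = np.array(obs), np.array(exp)
        exp_arr *= obs_arr.sum() / exp_arr.sum()  # condition on the total
        stat = ((obs_arr - exp_arr) ** 2 / exp_arr).sum()
        pvalue = stats.chi2.sf(stat, len(obs_arr) - 1)
        assert pvalue > 0.001


class TestCalibration:
    def test_fixed_point(self, calibrated_params, reference):
        agg = cs.expected_aggregates(calibrated_params, reference)
        targets = cs.CalibrationTargets(
            agg.deaths, agg.cause_deaths, agg.person_years, agg.smr_cause
        )
        out = cs.calibrate_cohort(targets, calibrated_params, reference)
        assert out.n_individuals == calibrated_params.n_individuals
        assert out.multiplier(50) == pytest.approx(calibrated_params.multiplier(50), rel=1e-9)
        assert out.cause_fraction(70) == pytest.approx(
            calibrated_params.cause_fraction(70), rel=1e-9
        )

    def test_small_targets_verified_by_monte_carlo(self, reference):
        """Calibrating to (100 deaths, 50 cause deaths, 10,000 PY, SMR 1.0)
        is verified against the mean of 200 simulated cohorts."""
        targets = cs.CalibrationTargets(100.0, 50.0, 10_000.0, 1.0)
        base = small_params(n_individuals=700, seed=0)
        rough = cs.calibrate_cohort(targets, base, reference, tol=0.49)
        # rescale the reference cause rates so expected cause deaths match
        # the SMR target (the cohort itself is unaffected by cause rates)
        agg = cs.expected_aggregates(rough, reference)
        ref = reference.copy()
        ref["cause_deaths"] *= targets.cause_deaths / targets.smr / agg.expected_cause
        params = cs.calibrate_cohort(targets, rough, ref, tol=0.02)

        agg = cs.expected_aggregates(params, ref)
        assert agg.person_years == pytest.approx(targets.person_years, rel=0.02)
        assert agg.deaths == pytest.approx(targets.total_deaths, rel=0.02)
        assert agg.cause_deaths == pytest.approx(targets.cause_deaths, rel=0.02)
        assert agg.smr_cause == pytest.approx(targets.smr, rel=0.02)

        deaths, causes, pys = [], [], []
        for seed in range(1, 201):
            sim = cs.generate_cohort(replace(params, seed=seed), ref)
            deaths.append(sum(1 for i in sim if i.status == "dead"))
            causes.append(sum(1 for i in sim if i.cause_of_interest))
            pys.append(sum(i.follow_up_years for i in sim))
        for values, target in ((deaths, 100.0), (causes, 50.0), (pys, 10_000.0)):
            arr = np.asarray(values, float)
            se = arr.std(ddof=1) / math.sqrt(len(arr))
            assert abs(arr.mean() - target) < 4.0 * se

    def test_inconsistent_smr_target_reports_residuals(self, reference):
        base = small_params(n_individuals=700, seed=0)
        targets = cs.CalibrationTargets(100.0, 50.0, 10_000.0, 3.0)  # unreachable SMR
        with pytest.raises(CalibrationError) as err:
            cs.calibrate_cohort(targets, base, reference, tol=0.02)
        assert "smr" in err.value.residuals


class TestCsvRoundTrip:
    def test_cohort(self, tmp_path, reference):
        cohort = cs.generate_cohort(small_params(n_individuals=50), reference)
        path = tmp_path / "cohort.csv"
        cs.cohort_to_csv(cohort, path)
        assert cs.cohort_from_csv(path) == cohort
        header = path.read_text().splitlines()[0]
        assert header == "id,birth_date,entry_date,exit_date,status,cause"

    def test_reference(self, tmp_path, reference):
        path = tmp_path / "reference.csv"
        cs.reference_to_csv(reference, path)
        back = cs.reference_from_csv(path)
        pd.testing.assert_frame_equal(back, reference)
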