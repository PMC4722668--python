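"""End-to-end pipeline: configuration, orchestration, report assembly.

``run_pipeline`` wires the stages together — reference table, calibrated
synthetic cohort, person-years stratification, observed SMR, the five
scenario bias surfaces, and a corrected-SMR summary table for the five
standard quality combinations — and writes everything to an output
directory together with a machine-readable manifest (SHA-256 checksums of
every output).  Deterministic given the master seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_synth as cs
from .exceptions import ConfigurationError
from .misclass_model import DiagnosticQuality, true_smr
from .person_years import build_stratum_table
from .scenario_grid import SCENARIOS, plot_surface, run_scenario
from .smr_engine import SMREstimate, compute_smr, expected_table

__all__ = [
    "DEFAULT_CONFIG",
    "default_config",
    "load_config",
    "run_pipeline",
    "make_table2_analogue",
    "quality_from_config",
]

log = logging.getLogger("smrbias")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "log_level": "INFO",
    "output_dir": "smrbias_out",
    "cohort": {
        "n_individuals": 3014,
        "entry_start": "1990-01-01",
        "entry_end": "1999-12-31",
        "follow_up_end": "2010-05-10",
        "entry_age": {"name": "truncnorm", "mean": 37.36, "sd": 19.0, "lower": 0.0, "upper": 85.0},
        "hazard_multiplier": 0.9668,
        "cause_fraction_scale": 0.847,
        "loss_rate": 0.00145,
        "calibrate": True,
        "targets": {"total_deaths": 251.0, "cause_deaths": 80.0, "person_years": 44000.0, "smr": 0.82},
        "calibration_tol": 0.02,
    },
    "reference": {"years": [1990, 2010], "band_width": 5, "max_age": 110},
    "quality": {
        "cohort": {"below": [0.85, 0.85], "above": [0.85, 0.85]},
        "reference": {"below": [0.85, 0.85], "above": [0.85, 0.85]},
        "cutoff": 70,
    },
    "scenarios": ["A", "B1", "B2", "B3", "B4"],
    "grid_step": 0.01,
    "alpha": 0.05,
    "clamp": True,
    "plots": False,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML/JSON file and a dict."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)  # YAML is a JSON superset
        if loaded:
            config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    return config


def quality_from_config(block: dict) -> tuple[DiagnosticQuality, DiagnosticQuality]:
    """Build (cohort, reference) quality from the ``quality:`` config block."""
    cutoff = int(block.get("cutoff", 70))

    def build(side: dict) -> DiagnosticQuality:
        se_b, sp_b = side["below"]
        se_a, sp_a = side["above"]
        return DiagnosticQuality(se_b, sp_b, se_a, sp_a, cutoff)

    return build(block["cohort"]), build(block["reference"])


def _params_from_config(config: dict, seed: int) -> cs.CohortParams:
    c = config["cohort"]
    age = c["entry_age"]
    model = cs.default_rate_model()
    fractions = cs.default_cause_fractions(
        model,
        scale=c.get("cause_fraction_scale", 0.847),
        band_width=config["reference"].get("band_width", 5),
        max_age=config["reference"].get("max_age", 110),
    )
    return cs.CohortParams(
        n_individuals=int(c["n_individuals"]),
        entry_start=date.fromisoformat(c["entry_start"]),
        entry_end=date.fromisoformat(c["entry_end"]),
        follow_up_end=date.fromisoformat(c["follow_up_end"]),
        entry_age=cs.AgeDistribution(
            name=age.get("name", "truncnorm"),
            mean=float(age.get("mean", 37.36)),
            sd=float(age.get("sd", 19.0)),
            lower=float(age.get("lower", 0.0)),
            upper=float(age.get("upper", 85.0)),
        ),
        hazard_multipliers=float(c.get("hazard_multiplier", 1.0)),
        cause_fraction_by_age=fractions,
        loss_rate=float(c.get("loss_rate", 0.0)),
        seed=seed,
        band_width=config["reference"].get("band_width", 5),
    )


def _reference_from_config(config: dict, seed: int) -> pd.DataFrame:
    r = config["reference"]
    lo, hi = r.get("years", [1990, 2010])
    width = r.get("band_width", 5)
    return cs.generate_reference(
        years=range(int(lo), int(hi) + 1),
        band_lowers=tuple(range(0, int(r.get("max_age", 110)), width)),
        model=cs.default_rate_model(),
        seed=seed,
        band_width=width,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


TABLE2_ROWS: list[tuple[str, tuple[float, float], tuple[float, float]]] = [
    ("non-differential", (0.70, 0.70), (0.70, 0.70)),
    ("differential", (0.70, 0.70), (0.85, 0.85)),
    ("differential", (0.85, 0.85), (0.70, 0.70)),
    ("differential", (0.85, 0.70), (0.70, 0.85)),
    ("differential", (0.70, 0.85), (0.85, 0.70)),
]


def make_table2_analogue(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    smr_observed: SMREstimate,
    rows=None,
    alpha: float = 0.05,
    cutoff_age: int = 70,
    below: tuple[float, float] = (0.85, 0.85),
    band_width: int = 5,
) -> pd.DataFrame:
    """Corrected SMR (with CI and significance flag) for the standard
    above-cutoff quality combinations, evaluated on the given tables."""
    rows = rows if rows is not None else TABLE2_ROWS
    se_b, sp_b = below
    records = []
    for kind, (c_se, c_sp), (r_se, r_sp) in rows:
        q_cohort = DiagnosticQuality(se_b, sp_b, c_se, c_sp, cutoff_age)
        q_reference = DiagnosticQuality(se_b, sp_b, r_se, r_sp, cutoff_age)
        est = true_smr(
            observed, expected, q_cohort, q_reference,
            alpha=alpha, clamp=True, band_width=band_width,
        )
        records.append(
            {
                "kind": kind,
                "cohort_se": c_se,
                "cohort_sp": c_sp,
                "reference_se": r_se,
                "reference_sp": r_sp,
                "smr_true": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "significant": est.significant,
                "bias_pct": 100.0 * (smr_observed.point - est.point) / est.point,
            }
        )
    return pd.DataFrame(records)


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the whole analysis; returns the manifest (also written to disk).

    Outputs: reference.csv, cohort.csv, strata.csv, smr_observed.json,
    smr_all_cause.json, surface_<label>.csv per scenario,
    corrected_smr_table.csv, manifest.json (+ optional surface PNGs).
    """
    config = config or default_config()
    seed = int(config["seed"])
    out = Path(out_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO"))))

    def stage(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        log.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
        return result

    reference = stage("reference", lambda: _reference_from_config(config, seed))
    params = _params_from_config(config, seed)
    c = config["cohort"]
    if c.get("calibrate", True):
        t = c["targets"]
        targets = cs.CalibrationTargets(
            t["total_deaths"], t["cause_deaths"], t["person_years"], t["smr"]
        )
        params = stage(
            "calibrate",
            lambda: cs.calibrate_cohort(
                targets, params, reference, tol=float(c.get("calibration_tol", 0.02))
            ),
        )
    cohort = stage("cohort", lambda: cs.generate_cohort(params, reference))
    strata = stage("person_years", lambda: build_stratum_table(cohort, params.band_width))
    expected = stage("expected", lambda: expected_table(reference, strata))
    alpha = float(config.get("alpha", 0.05))
    smr_obs = compute_smr(
        expected["cause_deaths"].sum(), expected["expected_cause_deaths"].sum(), alpha=alpha
    )
    smr_all = compute_smr(
        expected["all_cause_deaths"].sum(), expected["expected_all_cause_deaths"].sum(), alpha=alpha
    )

    outputs: dict[str, Path] = {}
    cs.reference_to_csv(reference, out / "reference.csv")
    outputs["reference"] = out / "reference.csv"
    cs.cohort_to_csv(cohort, out / "cohort.csv")
    outputs["cohort"] = out / "cohort.csv"
    expected.to_csv(out / "strata.csv", index=False)
    outputs["strata"] = out / "strata.csv"
    smr_obs.to_json(out / "smr_observed.json")
    outputs["smr_observed"] = out / "smr_observed.json"
    smr_all.to_json(out / "smr_all_cause.json")
    outputs["smr_all_cause"] = out / "smr_all_cause.json"

    labels = config.get("scenarios", list(SCENARIOS))
    for label in labels:
        try:
            spec = SCENARIOS[label]
        except KeyError:
            raise ConfigurationError(f"unknown scenario {label!r}") from None
        surface = stage(
            f"scenario {label}",
            lambda spec=spec: run_scenario(
                spec, expected, expected, smr_obs,
                grid_step=float(config.get("grid_step", 0.01)), alpha=alpha,
                band_width=params.band_width,
            ),
        )
        path = out / f"surface_{label}.csv"
        surface.to_csv(path, index=False)
        outputs[f"surface_{label}"] = path
        if config.get("plots", False):
            png = out / f"surface_{label}.png"
            plot_surface(surface, png, title=f"Scenario {label}")
            outputs[f"surface_{label}_png"] = png

    table2 = stage(
        "summary_table",
        lambda: make_table2_analogue(
            expected, expected, smr_obs, alpha=alpha,
            cutoff_age=int(config["quality"].get("cutoff", 70)),
            band_width=params.band_width,
        ),
    )
    table2.to_csv(out / "corrected_smr_table.csv", index=False)
    outputs["corrected_smr_table"] = out / "corrected_smr_table.csv"

    manifest = {
        "seed": seed,
        "n_individuals": params.n_individuals,
        "observed_smr": smr_obs.to_dict(),
        "all_cause_smr": smr_all.to_dict(),
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for name, p in outputs.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def dump_config(config: dict | None = None) -> str:
    return yaml.safe_dump(config or default_config(), sort_keys=False)
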