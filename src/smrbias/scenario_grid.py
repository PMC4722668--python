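"""Misclassification scenario grids and percent-bias surfaces.

Five scenarios span non-differential and differential certification
quality.  Below the age cut-off both populations keep SE = SP = 0.85; at
and above the cut-off the cohort's (SE, SP) sweep a grid over
[0.70, 0.85], while the reference population either mirrors the cohort
(scenario A, non-differential) or is fixed:

    A   reference mirrors cohort        (non-differential)
    B1  reference SE = SP = 0.85
    B2  reference SE = SP = 0.70
    B3  reference SE = 0.70, SP = 0.85
    B4  reference SE = 0.85, SP = 0.70

For each grid point the corrected ('true') SMR is computed and the bias is
the percent deviation of the originally observed SMR from it:
100 * (SMR_obs - SMR_true) / SMR_true — positive bias means the observed
SMR overstates the true one, i.e. attenuation toward the null for a
protective effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .misclass_model import (
    DiagnosticQuality,
    FLAG_CLAMPED_HIGH,
    FLAG_CLAMPED_LOW,
    FLAG_OK,
    corrected_totals,
)
from .smr_engine import SMREstimate, compute_smr

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "SURFACE_COLUMNS",
    "bias_pct",
    "run_scenario",
    "surface_sign_summary",
    "plot_surface",
]

SURFACE_COLUMNS = ["label", "se", "sp", "smr_true", "ci_low", "ci_high", "bias_pct", "flag"]

FLAG_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario table.

    ``reference_above`` is ``'mirror'`` (reference quality above the
    cut-off tracks the cohort's grid point — non-differential) or a fixed
    (SE, SP) pair (differential).
    """

    label: str
    below: tuple[float, float] = (0.85, 0.85)
    se_range: tuple[float, float] = (0.70, 0.85)
    sp_range: tuple[float, float] = (0.70, 0.85)
    reference_above: str | tuple[float, float] = "mirror"
    cutoff_age: int = 70

    def __post_init__(self):
        for lo, hi in (self.se_range, self.sp_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ConfigurationError(f"grid range ({lo}, {hi}) outside (0, 1]")
        if self.reference_above != "mirror":
            se, sp = self.reference_above
            if not (0.0 < se <= 1.0 and 0.0 < sp <= 1.0):
                raise ConfigurationError(f"reference quality {self.reference_above} invalid")

    def grid(self, step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
        if step <= 0:
            raise ConfigurationError("grid step must be positive")

        def axis(lo: float, hi: float) -> np.ndarray:
            n = int(round((hi - lo) / step)) + 1
            return np.round(np.linspace(lo, hi, n), 10)

        return axis(*self.se_range), axis(*self.sp_range)

    def qualities(self, se: float, sp: float) -> tuple[DiagnosticQuality, DiagnosticQuality]:
        """Cohort and reference quality at one grid point."""
        se_b, sp_b = self.below
        cohort = DiagnosticQuality(se_b, sp_b, se, sp, self.cutoff_age)
        if self.reference_above == "mirror":
            reference = cohort
        else:
            r_se, r_sp = self.reference_above
            reference = DiagnosticQuality(se_b, sp_b, r_se, r_sp, self.cutoff_age)
        return cohort, reference


SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", reference_above="mirror"),
    "B1": ScenarioSpec("B1", reference_above=(0.85, 0.85)),
    "B2": ScenarioSpec("B2", reference_above=(0.70, 0.70)),
    "B3": ScenarioSpec("B3", reference_above=(0.70, 0.85)),
    "B4": ScenarioSpec("B4", reference_above=(0.85, 0.70)),
}


def bias_pct(smr_observed: float, smr_true: float) -> float:
    """Percent deviation of the observed SMR from the corrected SMR."""
    if smr_true <= 0:
        raise DomainError(f"smr_true must be positive, got {smr_true}")
    return 100.0 * (smr_observed - smr_true) / smr_true


def run_scenario(
    spec: ScenarioSpec,
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    smr_observed: SMREstimate | float,
    grid_step: float = 0.01,
    alpha: float = 0.05,
    band_width: int = 5,
) -> pd.DataFrame:
    """Bias surface over the scenario's (SE, SP) grid.

    Band totals are formed once; each grid point corrects them with the
    scenario's cohort/reference quality and computes the corrected SMR, its
    exact Poisson CI, and the percent bias of the observed SMR.  Degenerate
    cells (corrected totals out of range) are clamped and flagged, never
    fatal.  Rows are sorted by (se, sp).
    """
    smr_obs_point = smr_observed.point if isinstance(smr_observed, SMREstimate) else smr_observed
    se_axis, sp_axis = spec.grid(grid_step)
    rows = []
    for se in se_axis:
        for sp in sp_axis:
            q_cohort, q_reference = spec.qualities(float(se), float(sp))
            flag = FLAG_OK
            try:
                corr_obs, d_total = corrected_totals(
                    observed, q_cohort, "cause_deaths", "all_cause_deaths", band_width
                )
                corr_exp, _ = corrected_totals(
                    expected,
                    q_reference,
                    "expected_cause_deaths",
                    "expected_all_cause_deaths",
                    band_width,
                )
                if corr_obs < 0.0:
                    corr_obs, flag = 0.0, FLAG_CLAMPED_LOW
                elif corr_obs > d_total:
                    corr_obs, flag = d_total, FLAG_CLAMPED_HIGH
                if corr_exp <= 0.0 or corr_obs <= 0.0:
                    raise DomainError("corrected totals not positive")
                est = compute_smr(corr_obs, corr_exp, alpha=alpha)
                rows.append(
                    {
                        "label": spec.label,
                        "se": float(se),
                        "sp": float(sp),
                        "smr_true": est.point,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "bias_pct": bias_pct(smr_obs_point, est.point),
                        "flag": flag,
                    }
                )
            except DomainError:
                rows.append(
                    {
                        "label": spec.label,
                        "se": float(se),
                        "sp": float(sp),
                        "smr_true": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "bias_pct": np.nan,
                        "flag": FLAG_DEGENERATE,
                    }
                )
    surface = pd.DataFrame(rows, columns=SURFACE_COLUMNS)
    return surface.sort_values(["se", "sp"]).reset_index(drop=True)


def surface_sign_summary(surface: pd.DataFrame) -> dict:
    """Sign structure of a bias surface.

    Per SP value: the minimal SE whose bias is non-negative (None when the
    whole SP column is negative); plus global min/max bias and the
    fractions of positive/negative/flagged cells.  Borderlines are reported
    at grid resolution.
    """
    ok = surface[surface["flag"] != FLAG_DEGENERATE]
    n = len(surface)
    borderline: dict[float, float | None] = {}
    for sp, column in ok.groupby("sp"):
        nonneg = column[column["bias_pct"] >= 0.0]
        borderline[float(sp)] = float(nonneg["se"].min()) if len(nonneg) else None
    return {
        "min_bias": float(ok["bias_pct"].min()) if len(ok) else None,
        "max_bias": float(ok["bias_pct"].max()) if len(ok) else None,
        "frac_positive": float((ok["bias_pct"] > 0).sum()) / n if n else 0.0,
        "frac_negative": float((ok["bias_pct"] < 0).sum()) / n if n else 0.0,
        "frac_flagged": float((surface["flag"] != FLAG_OK).sum()) / n if n else 0.0,
        "min_se_nonnegative_by_sp": borderline,
    }


def plot_surface(surface: pd.DataFrame, path, title: str | None = None) -> None:
    """Static 3-D rendering of a bias surface (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = surface.pivot(index="se", columns="sp", values="bias_pct")
    sp_grid, se_grid = np.meshgrid(pivot.columns.to_numpy(), pivot.index.to_numpy())
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(111, projection="3d")
    ax.plot_surface(se_grid, sp_grid, pivot.to_numpy(), cmap="viridis")
    ax.set_xlabel("SE (cohort, above cut-off)")
    ax.set_ylabel("SP (cohort, above cut-off)")
    ax.set_zlabel("bias [%]")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
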