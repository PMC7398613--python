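"""Lateralization: merging externally assumed variables into an SSD.

"Lateralization" transports an intervention measured in one population into
a model fitted on another: a new variable (here a monetary *rewards* nudge
in $/month, or an *engagement rate* in app messages/month) is appended to
the summary dataset with an assumed mean, SD, and cross-covariances, and
the path model is refitted.  Sensitivity scenarios S1–S4 then scale the
assumed lateral–adherence covariances by ±10% / ±20% and refit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pathmodel import (EffectsTable, PathFit, cd, decompose_effects,
                        effects_report, fit_path_model,
                        saturated_mediation_spec, srmr)
from .ssd import SSDError, SummaryDataset, symmetrize, validate_psd


class LateralizationError(ValueError):
    """Raised when appending or perturbing lateral variables fails."""


@dataclass(frozen=True)
class LateralVariable:
    """Externally assumed variable: mean, SD, and named cross-covariances.

    ``cross_cov`` values are on the covariance scale, taken literally from
    the assumed-moments table.  Keys may reference existing SSD variables or
    other laterals appended in the same call.
    """

    name: str
    mean: float
    sd: float
    cross_cov: Mapping[str, float] = field(default_factory=dict)
    units: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise LateralizationError(f"lateral {self.name!r} needs sd > 0")


def append_variables(
    ssd: SummaryDataset,
    laterals: Sequence[LateralVariable],
    treat_cross_as_correlation: bool = False,
    repair: bool = True,
) -> SummaryDataset:
    """Extend an SSD with lateral variables.

    Unspecified cross-covariances default to 0.  The result is symmetrized
    and PSD-validated (eigenvalue-clipping repair allowed by default; an
    irreparable matrix raises).  With ``treat_cross_as_correlation`` the
    cross entries are read as correlations and rescaled by the SD products —
    the alternative reading of an ambiguous published table.
    """
    names = list(ssd.names)
    for lat in laterals:
        if lat.name in names:
            raise LateralizationError(f"variable {lat.name!r} already present")
        names.append(lat.name)
    k0, k1 = ssd.k, len(names)
    cov = np.zeros((k1, k1))
    cov[:k0, :k0] = ssd.cov
    means = np.concatenate([ssd.means, [lat.mean for lat in laterals]])
    sds = np.concatenate([ssd.sds, [lat.sd for lat in laterals]])
    pos = {n: i for i, n in enumerate(names)}
    for lat in laterals:
        i = pos[lat.name]
        cov[i, i] = lat.sd ** 2
        for other, value in lat.cross_cov.items():
            if other not in pos:
                raise LateralizationError(
                    f"lateral {lat.name!r} references unknown variable {other!r}"
                )
            j = pos[other]
            if treat_cross_as_correlation:
                value = value * lat.sd * sds[j]
            cov[i, j] = cov[j, i] = value
    out = SummaryDataset(names=names, n=ssd.n, means=means, sds=sds, cov=cov)
    out, _ = symmetrize(out)
    try:
        out, diag = validate_psd(out, repair=repair)
    except SSDError as e:
        raise LateralizationError(str(e)) from e
    if diag.repaired:
        import warnings
        warnings.warn(
            f"lateralized covariance repaired to PSD (perturbation norm "
            f"{diag.perturbation_norm:.2e})", stacklevel=2)
    return out


def delete_variable(ssd: SummaryDataset, name: str) -> SummaryDataset:
    """Drop a variable; appending a lateral then deleting it round-trips exactly."""
    return ssd.subset([n for n in ssd.names if n != name])


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative perturbation of selected covariance cells."""

    label: str
    multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.multipliers.values()):
            raise LateralizationError("scenario factors must be > 0")


#: Lateral/adherence cells the sensitivity scenarios perturb.
SCENARIO_CELLS = tuple(itertools.product(("rewards", "engagement_rate"), ("mpr", "pdc")))

SCENARIO_FACTORS = {"S1": 1.1, "S2": 1.2, "S3": 0.9, "S4": 0.8}


def scenario_table() -> list[ScenarioSpec]:
    """BASELINE plus the four ±10% / ±20% lateral–adherence scenarios."""
    specs = [ScenarioSpec("BASELINE", {cell: 1.0 for cell in SCENARIO_CELLS})]
    for label, factor in SCENARIO_FACTORS.items():
        specs.append(ScenarioSpec(label, {cell: factor for cell in SCENARIO_CELLS}))
    return specs


def apply_scenario(ssd: SummaryDataset, scenario: ScenarioSpec) -> SummaryDataset:
    """Scale the scenario's covariance cells (and transposes); revalidate PSD."""
    out = ssd.copy()
    for (a, b), factor in scenario.multipliers.items():
        if a not in out.names or b not in out.names:
            raise LateralizationError(
                f"scenario {scenario.label} targets missing cell ({a!r}, {b!r})"
            )
        out.set(a, b, out.get(a, b) * factor)
    out, _ = validate_psd(out, repair=True)
    return out


# ---------------------------------------------------------------------------
# The 16-model battery
# ---------------------------------------------------------------------------

MEDIATORS = (
    "inpatient_hospitalizations",
    "er_visits",
    "pcp_office_visits",
    "specialist_office_visits",
    "other_outpatient_services",
    "pharmacy_fills",
)

BASE_EXOGENOUS = ("age", "qci_score")

#: Row order of the published total-effects tables.
REPORT_ROWS = list(MEDIATORS) + ["age", "qci_score", "rewards", "engagement_rate"]


@dataclass
class SemResult:
    index: int
    label: str
    outcome: str
    scenario: str
    fit: PathFit
    effects: EffectsTable
    srmr: float
    cd: float

    def report(self) -> pd.DataFrame:
        return effects_report(self.effects, self.fit.spec, predictors=REPORT_ROWS)


def _fit_one(ssd: SummaryDataset, exogenous: Sequence[str], outcome: str) -> tuple[PathFit, EffectsTable, float, float]:
    spec = saturated_mediation_spec(exogenous, MEDIATORS, outcome)
    fit = fit_path_model(ssd, spec)
    effects = decompose_effects(fit)
    return fit, effects, srmr(ssd, fit), cd(ssd, fit)


def run_sem_battery(
    ssd: SummaryDataset,
    laterals: Mapping[str, LateralVariable],
    scenarios: Sequence[ScenarioSpec] | None = None,
    outcomes: Sequence[str] = ("mpr", "pdc"),
) -> list[SemResult]:
    """Fit the full 16-model inventory.

    #1/#2: claims-only models (age, QCI) for MPR / PDC.
    #3/#4: + rewards.           #5/#6: + engagement rate.
    #7/#8: + both laterals.     #9–#16: scenarios S1, S2, S3, S4 x outcome,
    each refitting the doubly-lateralized model with perturbed
    lateral–adherence covariances.
    """
    if scenarios is None:
        scenarios = [s for s in scenario_table() if s.label != "BASELINE"]
    rewards = laterals["rewards"]
    engagement = laterals["engagement_rate"]
    ssd_r = append_variables(ssd, [rewards])
    # engagement alone: drop its cross-covariance with the absent rewards
    eng_solo = LateralVariable(
        engagement.name, engagement.mean, engagement.sd,
        {k: v for k, v in engagement.cross_cov.items() if k != "rewards"},
        engagement.units,
    )
    ssd_e = append_variables(ssd, [eng_solo])
    ssd_re = append_variables(ssd, [rewards, engagement])

    inventory: list[tuple[str, SummaryDataset, tuple[str, ...], str]] = []
    for outcome in outcomes:
        inventory.append(("claims-only", ssd, BASE_EXOGENOUS, outcome))
    for outcome in outcomes:
        inventory.append(("+rewards", ssd_r, BASE_EXOGENOUS + ("rewards",), outcome))
    for outcome in outcomes:
        inventory.append(("+engagement", ssd_e, BASE_EXOGENOUS + ("engagement_rate",), outcome))
    for outcome in outcomes:
        inventory.append(("+both", ssd_re, BASE_EXOGENOUS + ("rewards", "engagement_rate"), outcome))

    results: list[SemResult] = []
    for label, data, exog, outcome in inventory:
        fit, eff, s, c = _fit_one(data, exog, outcome)
        results.append(SemResult(len(results) + 1, label, outcome, "BASELINE", fit, eff, s, c))
    for scen in scenarios:
        perturbed = apply_scenario(ssd_re, scen)
        for outcome in outcomes:
            fit, eff, s, c = _fit_one(perturbed, BASE_EXOGENOUS + ("rewards", "engagement_rate"), outcome)
            results.append(SemResult(len(results) + 1, f"+both {scen.label}", outcome, scen.label, fit, eff, s, c))
    return results


def battery_summary(results: Sequence[SemResult], baseline: bool = True) -> pd.DataFrame:
    """Combined total-effects table (rows = predictors, columns = models).

    ``baseline=True`` lays out models #1–#8 (the main-results table);
    ``False`` lays out the scenario models #9–#16 (the sensitivity table).
    """
    wanted = [r for r in results if (r.scenario == "BASELINE") == baseline]
    out = {}
    for r in wanted:
        col = f"SEM #{r.index} ({r.outcome.upper()}) {'' if baseline else r.scenario}".strip()
        rep = r.report()
        out[col] = rep["total_effect"] + rep["stars"]
    return pd.DataFrame(out, index=REPORT_ROWS)
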