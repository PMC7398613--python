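"""Patient-level claims types, cohort filtering, and adherence metrics.

Adherence to controller medication is measured two ways, both computed
directly from pharmacy-fill records:

* **MPR** (medication possession ratio): total days of supply divided by the
  span from the first fill to the last fill plus the last fill's supply.
  Patients with fewer than two eligible fills are coded 0 — the variable-
  interval denominator is undefined for a single fill, and coding 0 keeps
  every patient usable in covariance computations.
* **PDC** (proportion of days covered): distinct calendar days covered by at
  least one eligible supply, divided by the observation window.  Overlapping
  supplies never double-count a day, so PDC <= 1 by construction.

Dates are integer day indices (0-based, days since the observation-period
start).  A fill on day ``d`` with ``s`` days of supply covers days
``d .. d+s-1`` inclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DrugClass(str, enum.Enum):
    """Controller-medication class of a pharmacy fill."""

    ICS = "ICS"
    LABA = "LABA"
    ICS_LABA_COMBO = "ICS_LABA_COMBO"
    OTHER = "OTHER"


#: Classes that count toward adherence and cohort inclusion.
CONTROLLER_CLASSES = frozenset({DrugClass.ICS, DrugClass.LABA, DrugClass.ICS_LABA_COMBO})


class PdcDenominator(str, enum.Enum):
    """Denominator conventions for PDC (both appear in the literature)."""

    FIRST_FILL_TO_PERIOD_END = "first_fill_to_period_end"
    FIRST_TO_LAST_FILL = "first_to_last_fill"


class InvalidInputError(ValueError):
    """Raised for malformed patient records or configurations."""


@dataclass(frozen=True)
class PharmacyClaim:
    patient_id: str
    fill_date: int
    days_supply: int
    drug_class: DrugClass = DrugClass.OTHER

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise InvalidInputError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.fill_date < 0:
            raise InvalidInputError(f"fill_date must be >= 0, got {self.fill_date}")


@dataclass(frozen=True)
class MedicalEventCounts:
    """Utilization counts over the observation period.

    ``length_of_stay`` is total inpatient days, meaningful only for patients
    with at least one hospitalization (``None`` otherwise).
    """

    inpatient_hospitalizations: int = 0
    er_visits: int = 0
    pcp_office_visits: int = 0
    specialist_office_visits: int = 0
    other_outpatient_services: int = 0
    length_of_stay: int | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "length_of_stay":
                if v is not None and v < 1:
                    raise InvalidInputError("length_of_stay must be absent or >= 1")
            elif v < 0:
                raise InvalidInputError(f"{f.name} must be >= 0")
        if self.length_of_stay is not None and self.inpatient_hospitalizations < 1:
            raise InvalidInputError("length_of_stay requires >= 1 hospitalization")


@dataclass
class PatientRecord:
    patient_id: str
    age_years: int
    qci_score: int
    events: MedicalEventCounts = field(default_factory=MedicalEventCounts)
    claims: list[PharmacyClaim] = field(default_factory=list)
    enrollment_months: int = 12
    has_asthma_dx: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.qci_score <= 33:
            raise InvalidInputError(f"qci_score must be in [0, 33], got {self.qci_score}")
        if self.age_years < 0:
            raise InvalidInputError("age_years must be >= 0")
        self.claims = sorted(self.claims, key=lambda c: c.fill_date)


# Quan-Charlson comorbidity index: weighted count of condition categories.
# Weights 1 / 2 / 3 / 6; each category counted at most once; max score 33.
QCI_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "connective_tissue_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_without_complications": 1,
    "hemiplegia_or_paraplegia": 2,
    "renal_disease": 2,
    "diabetes_with_complications": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_carcinoma": 6,
    "aids_hiv": 6,
}

QCI_MAX_SCORE = sum(QCI_WEIGHTS.values())  # 33


@dataclass(frozen=True)
class ConditionFlags:
    """One boolean per comorbidity category (each counted at most once)."""

    myocardial_infarction: bool = False
    congestive_heart_failure: bool = False
    peripheral_vascular_disease: bool = False
    cerebrovascular_disease: bool = False
    dementia: bool = False
    chronic_pulmonary_disease: bool = False
    connective_tissue_disease: bool = False
    peptic_ulcer_disease: bool = False
    mild_liver_disease: bool = False
    diabetes_without_complications: bool = False
    hemiplegia_or_paraplegia: bool = False
    renal_disease: bool = False
    diabetes_with_complications: bool = False
    malignancy: bool = False
    moderate_severe_liver_disease: bool = False
    metastatic_solid_carcinoma: bool = False
    aids_hiv: bool = False


@dataclass(frozen=True)
class AdherenceConfig:
    pdc_denominator_mode: PdcDenominator = PdcDenominator.FIRST_FILL_TO_PERIOD_END
    cap_at_one: bool = False
    eligible_classes: frozenset[DrugClass] = CONTROLLER_CLASSES
    observation_end: int = 365

    def __post_init__(self) -> None:
        if self.observation_end <= 0:
            raise InvalidInputError("observation_end must be > 0")


DEFAULT_ADHERENCE_CONFIG = AdherenceConfig()


def _eligible_claims(record: PatientRecord, config: AdherenceConfig) -> list[PharmacyClaim]:
    return [c for c in record.claims if c.drug_class in config.eligible_classes]


def compute_qci(flags: ConditionFlags) -> int:
    """Quan-Charlson comorbidity score: sum of category weights, range [0, 33]."""
    return sum(w for name, w in QCI_WEIGHTS.items() if getattr(flags, name))


def compute_mpr(record: PatientRecord, config: AdherenceConfig = DEFAULT_ADHERENCE_CONFIG) -> float:
    """Medication possession ratio over the eligible fills.

    MPR = sum(days_supply) / (last_fill - first_fill + last_days_supply).
    Patients with fewer than two eligible fills are coded 0.  Uncapped by
    default (overlapping supplies can push MPR above 1); ``cap_at_one`` caps.
    """
    claims = _eligible_claims(record, config)
    if len(claims) < 2:
        return 0.0
    first, last = claims[0], claims[-1]
    span = last.fill_date - first.fill_date + last.days_supply
    if span <= 0:
        raise InvalidInputError(
            f"patient {record.patient_id}: nonpositive fill span {span}"
        )
    mpr = sum(c.days_supply for c in claims) / span
    return min(mpr, 1.0) if config.cap_at_one else mpr


def covered_days(claims: Sequence[PharmacyClaim], end: int | None = None) -> int:
    """Number of distinct calendar days covered by >= 1 supply, truncated at ``end``."""
    n = 0
    cursor = -1  # last covered day seen
    for c in claims:  # claims sorted by fill_date
        lo = max(c.fill_date, cursor + 1)
        hi = c.fill_date + c.days_supply - 1
        if end is not None:
            hi = min(hi, end - 1)
        if hi >= lo:
            n += hi - lo + 1
            cursor = max(cursor, hi)
        else:
            cursor = max(cursor, min(hi, c.fill_date + c.days_supply - 1))
    return n


def compute_pdc(record: PatientRecord, config: AdherenceConfig = DEFAULT_ADHERENCE_CONFIG) -> float:
    """Proportion of days covered: distinct covered days / observation window.

    The numerator counts each calendar day at most once (no stockpile
    carry-forward) and is truncated at the denominator's end, so PDC <= 1.
    Zero eligible fills returns 0 (cohort construction requires >= 1 fill).
    """
    claims = _eligible_claims(record, config)
    if not claims:
        return 0.0
    first = claims[0]
    if config.pdc_denominator_mode is PdcDenominator.FIRST_FILL_TO_PERIOD_END:
        denom = config.observation_end - first.fill_date
        if denom <= 0:
            raise InvalidInputError(
                f"patient {record.patient_id}: observation_end {config.observation_end} "
                f"not after first fill {first.fill_date}"
            )
        end = config.observation_end
    else:
        last = claims[-1]
        denom = last.fill_date - first.fill_date + last.days_supply
        end = first.fill_date + denom
    return covered_days(claims, end=end) / denom


@dataclass
class ExclusionTally:
    """Records removed per inclusion criterion, applied sequentially."""

    no_asthma_dx: int = 0
    no_eligible_fill: int = 0
    under_age: int = 0
    insufficient_enrollment: int = 0

    @property
    def total_excluded(self) -> int:
        return (self.no_asthma_dx + self.no_eligible_fill + self.under_age
                + self.insufficient_enrollment)


def apply_cohort_criteria(
    records: Iterable[PatientRecord],
    min_age: int = 18,
    min_enrollment_months: int = 12,
    eligible_classes: frozenset[DrugClass] = CONTROLLER_CLASSES,
) -> tuple[list[PatientRecord], ExclusionTally]:
    """Apply the cohort inclusion criteria in order; first failure claims the record.

    Criteria: asthma diagnosis flag, >= 1 eligible controller fill,
    age >= ``min_age``, enrollment >= ``min_enrollment_months``.
    """
    kept: list[PatientRecord] = []
    tally = ExclusionTally()
    for r in records:
        if not r.has_asthma_dx:
            tally.no_asthma_dx += 1
        elif not any(c.drug_class in eligible_classes for c in r.claims):
            tally.no_eligible_fill += 1
        elif r.age_years < min_age:
            tally.under_age += 1
        elif r.enrollment_months < min_enrollment_months:
            tally.insufficient_enrollment += 1
        else:
            kept.append(r)
    return kept, tally


#: Canonical order of the ten modeled variables.
STUDY_VARIABLES = [
    "age",
    "inpatient_hospitalizations",
    "er_visits",
    "pcp_office_visits",
    "specialist_office_visits",
    "other_outpatient_services",
    "pharmacy_fills",
    "qci_score",
    "mpr",
    "pdc",
]


def patient_table(
    records: Sequence[PatientRecord],
    config: AdherenceConfig = DEFAULT_ADHERENCE_CONFIG,
) -> pd.DataFrame:
    """Per-patient table of the ten study variables (adherence recomputed from claims).

    ``pharmacy_fills`` counts all fills (any drug class), matching the
    all-medications dispensing variable; MPR/PDC use only eligible classes.
    """
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "age": r.age_years,
            "inpatient_hospitalizations": r.events.inpatient_hospitalizations,
            "er_visits": r.events.er_visits,
            "pcp_office_visits": r.events.pcp_office_visits,
            "specialist_office_visits": r.events.specialist_office_visits,
            "other_outpatient_services": r.events.other_outpatient_services,
            "pharmacy_fills": len(r.claims),
            "qci_score": r.qci_score,
            "mpr": compute_mpr(r, config),
            "pdc": compute_pdc(r, config),
        })
    return pd.DataFrame(rows).set_index("patient_id")


def summarize_cohort(
    records: Sequence[PatientRecord],
    config: AdherenceConfig = DEFAULT_ADHERENCE_CONFIG,
) -> pd.DataFrame:
    """Descriptive table (n, mean, SD, SE, median) per study variable.

    Length of stay is summarized only over patients with >= 1 hospitalization,
    since it is undefined for the rest.
    """
    if not len(records):
        raise InvalidInputError("cannot summarize an empty cohort")
    table = patient_table(records, config)
    rows = {}
    for name in STUDY_VARIABLES:
        x = table[name].to_numpy(dtype=float)
        rows[name] = _describe(x)
    los = np.array([
        float(r.events.length_of_stay)
        for r in records
        if r.events.inpatient_hospitalizations >= 1 and r.events.length_of_stay is not None
    ])
    if los.size:
        rows["length_of_stay"] = _describe(los)
    return pd.DataFrame(rows).T[["n", "mean", "sd", "se", "median"]]


def _describe(x: np.ndarray) -> dict[str, float]:
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": float(np.mean(x)),
        "sd": sd,
        "se": sd / math.sqrt(n),
        "median": float(np.median(x)),
    }


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

#: Observation-period start used to convert ISO fill dates to day indices.
DEFAULT_PERIOD_START = pd.Timestamp("2018-04-01")


def _to_day_index(values: pd.Series, period_start: pd.Timestamp) -> pd.Series:
    if pd.api.types.is_integer_dtype(values) or pd.api.types.is_float_dtype(values):
        return values.astype(int)
    days = (pd.to_datetime(values) - period_start).dt.days
    if (days < 0).any():
        raise InvalidInputError("fill dates before the observation-period start")
    return days


def read_claims_csv(path: str | Path, period_start: pd.Timestamp = DEFAULT_PERIOD_START) -> pd.DataFrame:
    """Read a fills table: patient_id, fill_date (ISO or day index), days_supply, drug_class."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "fill_date", "days_supply", "drug_class"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"claims file missing columns: {sorted(missing)}")
    if df.empty:
        raise InvalidInputError("claims file contains no fills")
    df["fill_date"] = _to_day_index(df["fill_date"], period_start)
    df["drug_class"] = df["drug_class"].map(lambda s: DrugClass(str(s)))
    return df


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-patient utilization-count table."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "inpatient_hospitalizations", "er_visits",
                "pcp_office_visits", "specialist_office_visits",
                "other_outpatient_services"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"events file missing columns: {sorted(missing)}")
    return df.set_index("patient_id")


def read_demographics_csv(path: str | Path) -> pd.DataFrame:
    """Read demographics: patient_id, age plus either qci_score or condition flags."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns or "age" not in df.columns:
        raise InvalidInputError("demographics file requires patient_id and age columns")
    df = df.set_index("patient_id")
    if "qci_score" not in df.columns:
        flag_cols = [c for c in df.columns if c in QCI_WEIGHTS]
        if not flag_cols:
            raise InvalidInputError("demographics need qci_score or condition-flag columns")
        df["qci_score"] = sum(df[c].astype(bool) * QCI_WEIGHTS[c] for c in flag_cols)
    return df


def records_from_tables(
    claims: pd.DataFrame,
    events: pd.DataFrame,
    demographics: pd.DataFrame,
) -> list[PatientRecord]:
    """Assemble patient records from the three claim-extract tables."""
    by_patient: dict[str, list[PharmacyClaim]] = {}
    for row in claims.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            PharmacyClaim(row.patient_id, int(row.fill_date), int(row.days_supply),
                          row.drug_class)
        )
    records = []
    for pid, demo in demographics.iterrows():
        ev = events.loc[pid] if pid in events.index else None
        los = None
        if ev is not None and "length_of_stay" in ev.index and pd.notna(ev["length_of_stay"]):
            los = int(ev["length_of_stay"])
        counts = MedicalEventCounts(
            inpatient_hospitalizations=int(ev["inpatient_hospitalizations"]) if ev is not None else 0,
            er_visits=int(ev["er_visits"]) if ev is not None else 0,
            pcp_office_visits=int(ev["pcp_office_visits"]) if ev is not None else 0,
            specialist_office_visits=int(ev["specialist_office_visits"]) if ev is not None else 0,
            other_outpatient_services=int(ev["other_outpatient_services"]) if ev is not None else 0,
            length_of_stay=los,
        )
        records.append(PatientRecord(
            patient_id=str(pid),
            age_years=int(demo["age"]),
            qci_score=int(demo["qci_score"]),
            events=counts,
            claims=by_patient.get(pid, []),
            enrollment_months=int(demo.get("enrollment_months", 12)),
            has_asthma_dx=bool(demo.get("has_asthma_dx", True)),
        ))
    return records
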