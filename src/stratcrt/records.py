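"""Prescription records: data model, eligibility, adherence, 2x2 tables.

The unit of observation is one dispensed-treatment event for a gonorrhea
diagnosis.  The national guideline regimen for uncomplicated gonorrhea is a
single 1 g (1000 mg) intramuscular dose of ceftriaxone; anything else —
different dose, repeated administration, non-IM route, or additional
antibiotics on the same prescription — is a deviation (nonadherence).

Eligibility screening applies five exclusion criteria before adjudication:

1. patient younger than 18 years;
2. pregnant or lactating patient;
3. no ceftriaxone on the prescription;
4. antibiotics prescribed for other (non-gonococcal) infections;
5. complicated gonorrhea (e.g. disseminated infection, PID).

Criteria are evaluated in this order; the first match is the *primary*
reason used in flow tallies, while all matching reasons are recorded on the
decision.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Sequence

from scipy import stats

from .errors import (
    ContractViolationError,
    DegenerateTableError,
    RecordValidationError,
    UndefinedPercentageError,
)

logger = logging.getLogger(__name__)


class Arm(str, Enum):
    control = "control"
    intervention = "intervention"


class Period(str, Enum):
    baseline = "baseline"
    endline = "endline"


class Sex(str, Enum):
    male = "male"
    female = "female"


class Diagnosis(str, Enum):
    uncomplicated_gonorrhea = "uncomplicated_gonorrhea"
    complicated_gonorrhea = "complicated_gonorrhea"


class Route(str, Enum):
    IM = "IM"
    IV = "IV"
    oral = "oral"
    other = "other"


class Indication(str, Enum):
    gonorrhea = "gonorrhea"
    other_infection = "other_infection"


#: Exclusion reasons in precedence order (first match = primary reason).
EXCLUSION_REASONS = (
    "under_18",
    "pregnant_or_lactating",
    "no_ceftriaxone",
    "other_infection_antibiotics",
    "complicated",
)

#: Default case-insensitive synonym list for the guideline drug.  Hospital
#: information systems are dialect-ridden; trade names map to the generic.
DEFAULT_CEFTRIAXONE_SYNONYMS = frozenset(
    {"ceftriaxone", "ceftriaxone sodium", "rocephin"}
)

GUIDELINE_DOSE_MG = 1000.0


@dataclass(frozen=True)
class DrugOrder:
    """One drug line on a prescription."""

    drug_name: str
    dose_mg: float
    route: Route | None
    n_administrations: int = 1
    indication: Indication = Indication.gonorrhea

    def __post_init__(self):
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty")
        if not self.dose_mg > 0:
            raise ValueError("dose_mg must be positive")
        if self.n_administrations < 1:
            raise ValueError("n_administrations must be >= 1")

    def matches(self, synonyms: frozenset[str]) -> bool:
        return self.drug_name.strip().lower() in synonyms


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed-treatment event with patient, physician and cluster context."""

    record_id: str
    cluster_id: str
    stratum: str
    arm: Arm
    period: Period
    patient_age: int
    patient_sex: Sex
    pregnant_or_lactating: bool
    diagnosis: Diagnosis
    drugs: tuple[DrugOrder, ...]
    physician_id: str

    def __post_init__(self):
        if self.patient_age < 0:
            raise RecordValidationError(self.record_id, "patient_age", "must be >= 0")


@dataclass(frozen=True)
class EligibilityDecision:
    record_id: str
    eligible: bool
    exclusion_reasons: frozenset[str]
    primary_reason: str | None = None

    def __post_init__(self):
        assert self.eligible == (len(self.exclusion_reasons) == 0)


@dataclass(frozen=True)
class AdherenceCall:
    """Adjudication of one eligible prescription against the guideline regimen.

    ``ambiguous`` marks prescriptions containing a correct ceftriaxone
    regimen plus an extra gonorrhea-indicated antibiotic: the guideline text
    does not address these, so the rule engine calls them deviations and
    flags them for human review.
    """

    record_id: str
    adherent: bool
    ambiguous: bool = False


@dataclass(frozen=True)
class PhysicianProfile:
    physician_id: str
    cluster_id: str
    sex: Sex
    age_group: str            # under_35 | 35_and_over
    degree: str               # postgrad_and_above | undergrad_and_below
    department: str           # dermatology | obgyn | urology | andrology | std
    service_years_band: str   # le5 | 6_10 | ge11
    title: str                # chief | associate_chief | in_charge | resident
    cases_last_3mo_band: str  # lt5 | ge5
    prior_training: bool

    _ENUMS = {
        "age_group": {"under_35", "35_and_over"},
        "degree": {"postgrad_and_above", "undergrad_and_below"},
        "department": {"dermatology", "obgyn", "urology", "andrology", "std"},
        "service_years_band": {"le5", "6_10", "ge11"},
        "title": {"chief", "associate_chief", "in_charge", "resident"},
        "cases_last_3mo_band": {"lt5", "ge5"},
    }

    def __post_init__(self):
        for name, allowed in self._ENUMS.items():
            value = getattr(self, name)
            if value not in allowed:
                raise RecordValidationError(self.physician_id, name,
                                            f"{value!r} not in {sorted(allowed)}")


@dataclass
class ArmPeriodFlow:
    """Flow tallies for one (arm, period) cell of the trial profile."""

    screened: int = 0
    eligible: int = 0
    excluded: Counter = field(default_factory=Counter)
    illegible: int = 0  # unparseable records, counted before screening

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    def conserved(self) -> bool:
        return self.screened == self.eligible + self.total_excluded


@dataclass
class FlowCounts:
    """Trial-profile accounting per (arm, period), mirroring a CONSORT flow."""

    cells: dict[tuple[Arm, Period], ArmPeriodFlow] = field(default_factory=dict)

    def cell(self, arm: Arm, period: Period) -> ArmPeriodFlow:
        return self.cells.setdefault((Arm(arm), Period(period)), ArmPeriodFlow())

    def conserved(self) -> bool:
        return all(c.conserved() for c in self.cells.values())

    def totals(self) -> ArmPeriodFlow:
        out = ArmPeriodFlow()
        for c in self.cells.values():
            out.screened += c.screened
            out.eligible += c.eligible
            out.illegible += c.illegible
            out.excluded.update(c.excluded)
        return out

    def to_dict(self) -> dict:
        return {
            f"{arm.value}/{period.value}": {
                "screened": c.screened,
                "eligible": c.eligible,
                "illegible": c.illegible,
                "excluded": {r: c.excluded.get(r, 0) for r in EXCLUSION_REASONS},
            }
            for (arm, period), c in sorted(
                self.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        }


def _exclusion_reasons(
    record: PrescriptionRecord, synonyms: frozenset[str]
) -> list[str]:
    reasons = []
    if record.patient_age < 18:
        reasons.append("under_18")
    if record.pregnant_or_lactating:
        reasons.append("pregnant_or_lactating")
    if not any(d.matches(synonyms) for d in record.drugs):
        reasons.append("no_ceftriaxone")
    if any(d.indication is Indication.other_infection for d in record.drugs):
        reasons.append("other_infection_antibiotics")
    if record.diagnosis is Diagnosis.complicated_gonorrhea:
        reasons.append("complicated")
    return reasons


def filter_eligible(
    records: Sequence[PrescriptionRecord],
    synonyms: Iterable[str] | None = None,
) -> tuple[list[EligibilityDecision], FlowCounts]:
    """Screen records against the five exclusion criteria.

    Returns one :class:`EligibilityDecision` per record plus
    :class:`FlowCounts` tallies per (arm, period), with the primary
    exclusion reason assigned by first match in precedence order.
    """
    syn = _normalize_synonyms(synonyms)
    decisions: list[EligibilityDecision] = []
    flow = FlowCounts()
    for rec in records:
        reasons = _exclusion_reasons(rec, syn)
        cell = flow.cell(rec.arm, rec.period)
        cell.screened += 1
        if reasons:
            cell.excluded[reasons[0]] += 1
            decisions.append(
                EligibilityDecision(rec.record_id, False, frozenset(reasons), reasons[0])
            )
        else:
            cell.eligible += 1
            decisions.append(EligibilityDecision(rec.record_id, True, frozenset()))
    return decisions, flow


def _normalize_synonyms(synonyms: Iterable[str] | None) -> frozenset[str]:
    if synonyms is None:
        return DEFAULT_CEFTRIAXONE_SYNONYMS
    return frozenset(s.strip().lower() for s in synonyms)


def adjudicate_adherence(
    record: PrescriptionRecord,
    synonyms: Iterable[str] | None = None,
    override: bool | None = None,
) -> AdherenceCall:
    """Adjudicate one *eligible* record against the guideline regimen.

    Adherent iff the prescription's ceftriaxone orders consist of exactly
    one order, given once (``n_administrations == 1``), at 1000 mg, by the
    IM route, with no additional gonorrhea-indicated antibiotic.

    ``override`` models the second independent reviewer: when given and it
    disagrees with the rule engine, the rule engine's call stands but the
    record is flagged ambiguous so the disagreement surfaces in reports.
    """
    syn = _normalize_synonyms(synonyms)
    cef = [d for d in record.drugs if d.matches(syn)]
    if not cef:
        raise ContractViolationError(
            f"record {record.record_id!r} has no ceftriaxone order; "
            "adjudication is defined only for eligible records"
        )
    extra_antibiotics = [d for d in record.drugs if not d.matches(syn)]

    regimen_ok = (
        len(cef) == 1
        and cef[0].n_administrations == 1
        and cef[0].dose_mg == GUIDELINE_DOSE_MG
        and cef[0].route is Route.IM
    )
    if len(cef) == 1 and cef[0].route is None:
        logger.warning(
            "record %s: ceftriaxone route missing; treated as deviation",
            record.record_id,
        )
    ambiguous = regimen_ok and bool(extra_antibiotics)
    adherent = regimen_ok and not extra_antibiotics
    if override is not None and override != adherent:
        ambiguous = True
    return AdherenceCall(record.record_id, adherent, ambiguous)


def adherence_table(
    decisions: Sequence[EligibilityDecision],
    calls: Sequence[AdherenceCall],
    records: Sequence[PrescriptionRecord],
):
    """Aggregate adjudicated records into per-(cluster, period) counts.

    Returns a pandas DataFrame with one row per (cluster_id, period) for
    every cluster appearing in ``records`` (clusters with no eligible
    records in a period are retained with o = n = 0 and ``flagged`` True),
    carrying ``o`` (adherent count), ``n`` (eligible count), ``p`` (o/n or
    NaN) and the cluster's stratum/arm labels.
    """
    import pandas as pd

    eligible_ids = {d.record_id for d in decisions if d.eligible}
    call_by_id = {c.record_id: c for c in calls}
    missing = eligible_ids - set(call_by_id)
    if missing:
        raise ContractViolationError(
            f"{len(missing)} eligible records lack adherence calls "
            f"(e.g. {sorted(missing)[:3]})"
        )

    clusters: dict[tuple[str, Period], dict] = {}
    meta: dict[str, tuple[str, Arm]] = {}
    for rec in records:
        prev = meta.get(rec.cluster_id)
        if prev is not None and prev != (rec.stratum, rec.arm):
            raise RecordValidationError(
                rec.record_id, "cluster_id",
                f"inconsistent (stratum, arm) for cluster {rec.cluster_id!r}",
            )
        meta[rec.cluster_id] = (rec.stratum, rec.arm)
        for period in Period:
            clusters.setdefault((rec.cluster_id, period), {"o": 0, "n": 0})
    for rec in records:
        if rec.record_id in eligible_ids:
            cell = clusters[(rec.cluster_id, rec.period)]
            cell["n"] += 1
            cell["o"] += int(call_by_id[rec.record_id].adherent)

    rows = []
    for (cluster_id, period), cell in clusters.items():
        stratum, arm = meta[cluster_id]
        o, n = cell["o"], cell["n"]
        rows.append({
            "cluster_id": cluster_id,
            "stratum": stratum,
            "arm": arm.value,
            "period": period.value,
            "o": o,
            "n": n,
            "p": o / n if n > 0 else math.nan,
            "flagged": n == 0,
        })
    df = pd.DataFrame(rows).sort_values(
        ["stratum", "arm", "cluster_id", "period"], ignore_index=True
    )
    return df


def report_percentage(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Format 100*numerator/denominator the way trial reports print it.

    Rounds half away from zero to ``decimals`` places; with ``decimals=1``
    a trailing ``.0`` is dropped (1240/2954 prints as ``"42%"``).
    """
    if denominator == 0:
        raise UndefinedPercentageError("percentage undefined: denominator is 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounded = value.quantize(quantum, rounding=ROUND_HALF_UP)
    text = f"{rounded:f}"
    if decimals == 1 and text.endswith(".0"):
        text = text[:-2]
    return text + "%"


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane–Anscombe 0.5 applied to all four cells


def crude_odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Unadjusted odds ratio for a 2x2 table with Woolf log-scale CI.

    Cells are (a, b) in the first row and (c, d) in the second; the odds
    ratio is ad/bc.  Any zero cell triggers the Haldane–Anscombe 0.5
    continuity correction on all four cells for the OR and CI.  A zero row
    or column margin is degenerate and raises.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(f"2x2 table ({a},{b},{c},{d}) has a zero margin")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 if corrected else float(x) for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    log_or = math.log(or_)
    ci_low, ci_high = math.exp(log_or - z * se_log), math.exp(log_or + z * se_log)
    p = 2 * stats.norm.sf(abs(log_or) / se_log)
    return OddsRatioResult(or_, ci_low, ci_high, p, corrected)
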