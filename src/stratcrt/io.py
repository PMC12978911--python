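"""Delimited-text input/output for prescription and physician tables.

Prescription CSV schema (UTF-8, comma, header row): record_id, cluster_id,
stratum, arm, period, patient_age, patient_sex, pregnant_or_lactating,
diagnosis, drugs, physician_id.  The ``drugs`` column packs the order list
as ``name:dose_mg:route:n_administrations:indication`` items joined by
``|`` (empty string = no orders).  Booleans are ``True``/``False`` (case
insensitive; 1/0 accepted).

Physician CSV schema: physician_id, cluster_id, sex, age_group, degree,
department, service_years_band, title, cases_last_3mo_band, prior_training.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import RecordValidationError
from .records import (
    Arm,
    Diagnosis,
    DrugOrder,
    Indication,
    Period,
    PhysicianProfile,
    PrescriptionRecord,
    Route,
    Sex,
)

PRESCRIPTION_COLUMNS = [
    "record_id", "cluster_id", "stratum", "arm", "period", "patient_age",
    "patient_sex", "pregnant_or_lactating", "diagnosis", "drugs", "physician_id",
]

PHYSICIAN_COLUMNS = [
    "physician_id", "cluster_id", "sex", "age_group", "degree", "department",
    "service_years_band", "title", "cases_last_3mo_band", "prior_training",
]


@dataclass(frozen=True)
class InvalidRecord:
    record_id: str
    field: str
    message: str


def parse_drugs(text: str) -> tuple[DrugOrder, ...]:
    text = (text or "").strip()
    if not text:
        return ()
    orders = []
    for item in text.split("|"):
        parts = item.split(":")
        if len(parts) != 5:
            raise ValueError(f"malformed drug item {item!r}")
        name, dose, route, n_adm, indication = parts
        orders.append(DrugOrder(
            drug_name=name,
            dose_mg=float(dose),
            route=Route(route) if route else None,
            n_administrations=int(n_adm),
            indication=Indication(indication),
        ))
    return tuple(orders)


def format_drugs(orders: tuple[DrugOrder, ...]) -> str:
    return "|".join(
        f"{o.drug_name}:{o.dose_mg:g}:{o.route.value if o.route else ''}"
        f":{o.n_administrations}:{o.indication.value}"
        for o in orders
    )


def _parse_bool(value, field: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {field}={value!r}")


def records_from_frame(
    df: pd.DataFrame,
) -> tuple[list[PrescriptionRecord], list[InvalidRecord]]:
    """Parse a prescription table, collecting unparseable rows.

    Rows with a missing or malformed required field (e.g. corrupted,
    "illegible" records) are returned separately so the flow report can
    count them; they never reach eligibility screening.
    """
    missing_cols = [c for c in PRESCRIPTION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordValidationError("<table>", missing_cols[0], "column missing")
    records: list[PrescriptionRecord] = []
    invalid: list[InvalidRecord] = []
    for row in df.itertuples(index=False):
        rid = str(getattr(row, "record_id", ""))
        current_field = "record_id"
        try:
            fields = {}
            for col in PRESCRIPTION_COLUMNS:
                current_field = col
                value = getattr(row, col)
                if value is None or (isinstance(value, float) and pd.isna(value)) or (
                    isinstance(value, str) and not value.strip() and col != "drugs"
                ):
                    raise ValueError("missing value")
                fields[col] = value
            current_field = "drugs"
            drugs = parse_drugs(str(fields["drugs"]) if not pd.isna(fields["drugs"]) else "")
            records.append(PrescriptionRecord(
                record_id=str(fields["record_id"]),
                cluster_id=str(fields["cluster_id"]),
                stratum=str(fields["stratum"]),
                arm=Arm(str(fields["arm"])),
                period=Period(str(fields["period"])),
                patient_age=int(fields["patient_age"]),
                patient_sex=Sex(str(fields["patient_sex"])),
                pregnant_or_lactating=_parse_bool(
                    fields["pregnant_or_lactating"], "pregnant_or_lactating"
                ),
                diagnosis=Diagnosis(str(fields["diagnosis"])),
                drugs=drugs,
                physician_id=str(fields["physician_id"]),
            ))
        except (ValueError, RecordValidationError) as exc:
            invalid.append(InvalidRecord(rid, current_field, str(exc)))
    return records, invalid


def read_prescriptions(path) -> tuple[list[PrescriptionRecord], list[InvalidRecord]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(df)


def write_prescriptions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "cluster_id": r.cluster_id,
            "stratum": r.stratum,
            "arm": r.arm.value,
            "period": r.period.value,
            "patient_age": r.patient_age,
            "patient_sex": r.patient_sex.value,
            "pregnant_or_lactating": r.pregnant_or_lactating,
            "diagnosis": r.diagnosis.value,
            "drugs": format_drugs(r.drugs),
            "physician_id": r.physician_id,
        })
    return pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS)


def read_physicians(path) -> pd.DataFrame:
    """Read and validate a physician roster; raises on any malformed row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_physicians(df)


def validate_physicians(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PHYSICIAN_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordValidationError("<roster>", missing_cols[0], "column missing")
    out = df[PHYSICIAN_COLUMNS].copy()
    out["prior_training"] = [
        _parse_bool(v, "prior_training") for v in out["prior_training"]
    ]
    for row in out.itertuples(index=False):
        PhysicianProfile(
            physician_id=str(row.physician_id),
            cluster_id=str(row.cluster_id),
            sex=Sex(str(row.sex)),
            age_group=str(row.age_group),
            degree=str(row.degree),
            department=str(row.department),
            service_years_band=str(row.service_years_band),
            title=str(row.title),
            cases_last_3mo_band=str(row.cases_last_3mo_band),
            prior_training=bool(row.prior_training),
        )
    return out
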