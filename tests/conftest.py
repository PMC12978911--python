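import pandas as pd
import pytest
from hypothesis import settings

from stratcrt.records import (
    Arm,
    Diagnosis,
    DrugOrder,
    Indication,
    Period,
    PrescriptionRecord,
    Route,
    Sex,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(
    record_id="r1",
    cluster_id="h1",
    stratum="prov_a",
    arm="control",
    period="endline",
    patient_age=30,
    patient_sex="male",
    pregnant_or_lactating=False,
    diagnosis="uncomplicated_gonorrhea",
    drugs=None,
    physician_id="p1",
):
    if drugs is None:
        drugs = [cef()]
    return PrescriptionRecord(
        record_id=record_id,
        cluster_id=cluster_id,
        stratum=stratum,
        arm=Arm(arm),
        period=Period(period),
        patient_age=patient_age,
        patient_sex=Sex(patient_sex),
        pregnant_or_lactating=pregnant_or_lactating,
        diagnosis=Diagnosis(diagnosis),
        drugs=tuple(drugs),
        physician_id=physician_id,
    )


def cef(dose=1000.0, route=Route.IM, n=1, indication=Indication.gonorrhea,
        name="ceftriaxone"):
    return DrugOrder(drug_name=name, dose_mg=dose, route=route,
                     n_administrations=n, indication=indication)


def drug(name, dose=1000.0, route=Route.oral, n=1,
         indication=Indication.gonorrhea):
    return DrugOrder(drug_name=name, dose_mg=dose, route=route,
                     n_administrations=n, indication=indication)


@pytest.fixture
def six_records():
    """Five records each violating exactly one exclusion criterion, plus one clean."""
    return [
        make_record("r_age", patient_age=16),
        make_record("r_preg", patient_sex="female", pregnant_or_lactating=True),
        make_record("r_nocef", drugs=[drug("azithromycin")]),
        make_record("r_otherinf", drugs=[
            cef(), drug("doxycycline", dose=100, n=14,
                        indication=Indication.other_infection)]),
        make_record("r_compl", diagnosis="complicated_gonorrhea"),
        make_record("r_clean"),
    ]


@pytest.fixture
def oracle_summaries():
    """One stratum, proportions {0.6, 0.4} vs {0.3, 0.2}: RR 2.0, RD 0.25."""
    return pd.DataFrame({
        "cluster_id": ["a", "b", "c", "d"],
        "stratum": ["s1"] * 4,
        "arm": ["intervention", "intervention", "control", "control"],
        "period": ["endline"] * 4,
        "o": [6, 4, 3, 2],
        "n": [10, 10, 10, 10],
    })
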