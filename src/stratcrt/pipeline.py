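"""End-to-end primary-outcome analysis: filter, adjudicate, estimate.

``primary_analysis`` runs the intention-to-treat pipeline the trial
pre-specified: eligibility screening, guideline adjudication, per-cluster
summaries, unadjusted stratified risk ratio and risk difference at
endline, a covariate-adjusted rerun on ratio/difference residuals from an
individual-level logistic model (fitted without a treatment term), and
within-arm paired t-tests of the endline-minus-baseline cluster changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import inference, records as rec
from .errors import ValidationError
from .records import AdherenceCall, FlowCounts, PrescriptionRecord

logger = logging.getLogger(__name__)

#: Covariates of interest for the adjusted analysis: province stratum,
#: cluster-level baseline adherence, patient sex and age, physician sex
#: and department.
DEFAULT_COVARIATES = [
    "stratum", "p_baseline", "patient_sex", "patient_age",
    "physician_sex", "physician_department",
]


class AnalysisConfig(BaseModel):
    """Knobs of the primary analysis."""

    alpha: float = Field(default=0.05, gt=0, lt=1)
    covariates: list[str] = Field(default_factory=lambda: list(DEFAULT_COVARIATES))
    synonyms: list[str] | None = None
    small_stratum: str = "error"     # or "merge_smallest"


@dataclass
class PrimaryAnalysisResult:
    flow: FlowCounts
    summaries: pd.DataFrame                 # per (cluster, period) with o, n, p
    estimates: dict[str, inference.EffectEstimate]
    strata: dict[str, list[inference.StratumEstimate]]
    paired: dict[str, inference.PairedChangeResult]
    rates: dict[str, dict]                  # arm/period -> {o, n, p}
    model: inference.CovariateModel | None
    n_ambiguous: int = 0
    meta: dict = field(default_factory=dict)


def _adherence_rates(summaries: pd.DataFrame) -> dict[str, dict]:
    out = {}
    for (arm, period), g in summaries.groupby(["arm", "period"]):
        o, n = int(g["o"].sum()), int(g["n"].sum())
        out[f"{arm}/{period}"] = {"o": o, "n": n, "p": o / n if n else None}
    return out


def primary_analysis(
    prescriptions: list[PrescriptionRecord],
    physicians: pd.DataFrame,
    config: AnalysisConfig | None = None,
    n_illegible: int = 0,
) -> PrimaryAnalysisResult:
    """Run the full primary-outcome analysis on validated records.

    Clusters are analysed under their recorded (original) allocation —
    intention to treat.  ``n_illegible`` carries the count of records that
    failed upstream validation, for the flow report only.
    """
    config = config or AnalysisConfig()
    decisions, flow = rec.filter_eligible(prescriptions, config.synonyms)
    eligible_ids = {d.record_id for d in decisions if d.eligible}
    calls: list[AdherenceCall] = [
        rec.adjudicate_adherence(r, config.synonyms)
        for r in prescriptions if r.record_id in eligible_ids
    ]
    summaries = rec.adherence_table(decisions, calls, prescriptions)

    # baseline cluster-level adherence as a covariate for the endline model
    base = summaries[summaries["period"] == "baseline"].set_index("cluster_id")
    p_baseline = base["p"]
    if p_baseline.isna().any():
        fill = base.groupby("stratum")["p"].transform(
            lambda s: s.fillna(s.mean())
        )
        p_baseline = fill
        logger.warning("baseline proportion missing for %d clusters; "
                       "filled with stratum mean", int(base["p"].isna().sum()))
    endline = summaries[summaries["period"] == "endline"].copy()
    endline["p_baseline"] = endline["cluster_id"].map(p_baseline)

    rr, rr_strata = inference.stratified_risk_ratio(
        endline, alpha=config.alpha, small_stratum=config.small_stratum
    )
    rd, rd_strata = inference.stratified_risk_difference(
        endline, alpha=config.alpha, small_stratum=config.small_stratum
    )

    individuals = _individual_table(
        prescriptions, eligible_ids, calls, physicians, p_baseline
    )
    X = inference.build_design_matrix(individuals, config.covariates)
    model = inference.fit_covariate_model(X, individuals["y"].to_numpy())
    endline_res = inference.residualize(endline, model, individuals)
    cov = tuple(config.covariates)
    rr_adj, rr_adj_strata = inference.stratified_risk_ratio(
        endline_res, use_residuals=True, alpha=config.alpha,
        covariates=cov, small_stratum=config.small_stratum,
    )
    rd_adj, rd_adj_strata = inference.stratified_risk_difference(
        endline_res, use_residuals=True, alpha=config.alpha,
        covariates=cov, small_stratum=config.small_stratum,
    )

    paired = {}
    for arm in ("control", "intervention"):
        try:
            paired[arm] = inference.paired_change_test(summaries, arm, config.alpha)
        except ValidationError as exc:
            logger.warning("paired test skipped for %s: %s", arm, exc)

    return PrimaryAnalysisResult(
        flow=flow,
        summaries=summaries,
        estimates={
            "rr_unadjusted": rr, "rd_unadjusted": rd,
            "rr_adjusted": rr_adj, "rd_adjusted": rd_adj,
        },
        strata={
            "rr_unadjusted": rr_strata, "rd_unadjusted": rd_strata,
            "rr_adjusted": rr_adj_strata, "rd_adjusted": rd_adj_strata,
        },
        paired=paired,
        rates=_adherence_rates(summaries),
        model=model,
        n_ambiguous=sum(c.ambiguous for c in calls),
        meta={"n_illegible": n_illegible,
              "n_eligible": len(eligible_ids),
              "n_screened": len(prescriptions)},
    )


def _individual_table(
    prescriptions, eligible_ids, calls, physicians: pd.DataFrame, p_baseline
) -> pd.DataFrame:
    """Endline eligible individuals with outcome and covariates."""
    call_by_id = {c.record_id: c for c in calls}
    rows = []
    for r in prescriptions:
        if r.record_id in eligible_ids and r.period.value == "endline":
            rows.append({
                "record_id": r.record_id,
                "cluster_id": r.cluster_id,
                "stratum": r.stratum,
                "patient_sex": r.patient_sex.value,
                "patient_age": r.patient_age,
                "physician_id": r.physician_id,
                "y": int(call_by_id[r.record_id].adherent),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no eligible endline records")
    phys = physicians.rename(
        columns={"sex": "physician_sex", "department": "physician_department"}
    )[["physician_id", "physician_sex", "physician_department"]]
    merged = df.merge(phys, on="physician_id", how="left", validate="many_to_one")
    if merged["physician_sex"].isna().any():
        missing = merged.loc[merged["physician_sex"].isna(), "physician_id"].unique()
        raise ValidationError(f"physicians missing from roster: {list(missing)[:5]}")
    merged["p_baseline"] = merged["cluster_id"].map(p_baseline)
    if merged["p_baseline"].isna().any():
        raise ValidationError("baseline proportion undefined for some clusters")
    return merged
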