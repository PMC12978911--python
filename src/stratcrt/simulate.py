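"""Synthetic stratified cluster-randomized trials of prescribing adherence.

The generator mirrors the structure the cluster-level analysis assumes:

* provinces (strata) with heterogeneous control-arm baseline adherence
  (real-world analogues range from about 4% to 77%);
* between-cluster variation as a multiplicative gamma effect on the risk
  scale with mean 1 and coefficient of variation ``k`` (the sample-size
  tradition defines k as the CV of true cluster proportions, so gamma on
  the risk scale — not logit-normal — is the matching mixing law), shared
  by a cluster's two periods so the baseline proportion is an informative
  covariate;
* an intervention effect that multiplies risk (the geometric-mean
  risk-ratio estimand) in intervention clusters at endline;
* physician covariate effects on the *odds* of nonadherence (the scale on
  which factor analyses report them), applied as per-record logit offsets
  centred at their population expectation so the cluster-level estimand is
  preserved;
* ineligible-record contamination matching the five exclusion criteria,
  and record corruption ("illegible prescriptions") that fails validation.

Cluster true proportions are clamped to [EPS, 1-EPS]; clamping is counted
in the truth record when it occurs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .errors import ValidationError

EPS = 1e-4

#: Marginal covariate frequencies used to draw physician rosters,
#: patterned on the control-arm physician characteristics of a large
#: multi-province prescribing study.
PHYSICIAN_FREQS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.458, "female": 0.542},
    "age_group": {"under_35": 0.373, "35_and_over": 0.627},
    "degree": {"postgrad_and_above": 0.373, "undergrad_and_below": 0.627},
    "department": {
        "dermatology": 0.230,
        "obgyn": 0.322,
        "urology": 0.274,
        "andrology": 0.044,
        "std": 0.130,
    },
    "service_years_band": {"le5": 0.257, "6_10": 0.213, "ge11": 0.530},
    "title": {"chief": 0.127, "associate_chief": 0.278, "in_charge": 0.391,
              "resident": 0.204},
    "cases_last_3mo_band": {"lt5": 0.982, "ge5": 0.018},
    "prior_training": {"True": 0.633, "False": 0.367},
}

EXCLUSION_ORDER = (
    "under_18",
    "pregnant_or_lactating",
    "no_ceftriaxone",
    "other_infection_antibiotics",
    "complicated",
)

_ADHERENT_DRUGS = "ceftriaxone:1000:IM:1:gonorrhea"
_DEVIATIONS = (
    "ceftriaxone:2000:IM:1:gonorrhea",                                # 2 g dose
    "ceftriaxone:1000:IM:3:gonorrhea",                                # repeated
    "ceftriaxone:1000:IV:1:gonorrhea",                                # wrong route
    "ceftriaxone:1000:IM:1:gonorrhea|azithromycin:1000:oral:1:gonorrhea",
)
_INELIGIBLE_DRUGS = {
    "under_18": _ADHERENT_DRUGS,
    "pregnant_or_lactating": _ADHERENT_DRUGS,
    "no_ceftriaxone": "azithromycin:1000:oral:1:gonorrhea",
    "other_infection_antibiotics":
        "ceftriaxone:1000:IM:1:gonorrhea|doxycycline:100:oral:14:other_infection",
    "complicated": "ceftriaxone:1000:IM:1:gonorrhea",
}


class StratumConfig(BaseModel):
    """One province stratum: control-arm baseline adherence and optional drift.

    ``drift`` multiplies both arms' risk at endline (secular trend);
    default 1 (no drift).
    """

    name: str
    baseline_p: float = Field(gt=0, lt=1)
    drift: float = Field(default=1.0, gt=0)


class SimulationConfig(BaseModel):
    """Full generative specification of one synthetic trial."""

    strata: list[StratumConfig]
    clusters_per_arm_per_stratum: int = Field(ge=1)
    prescriptions_per_cluster: float = Field(gt=0)   # Poisson mean, screened records
    true_rr: float = Field(gt=0)                     # endline intervention risk ratio
    k: float = Field(ge=0)                           # CV of true cluster proportions
    physician_effects: dict[str, float] = {}         # "column=level" -> OR(nonadherence)
    ineligible_fractions: dict[str, float] = {}      # exclusion reason -> probability
    loss_fraction: float = Field(default=0.0, ge=0, lt=1)
    physicians_per_cluster: int = Field(default=10, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for reason, frac in self.ineligible_fractions.items():
            if reason not in EXCLUSION_ORDER:
                raise ValueError(f"unknown exclusion reason {reason!r}")
            if not 0 <= frac < 1:
                raise ValueError(f"fraction for {reason!r} outside [0,1)")
        if sum(self.ineligible_fractions.values()) >= 1:
            raise ValueError("ineligible fractions sum to >= 1")
        for key, or_ in self.physician_effects.items():
            if "=" not in key:
                raise ValueError(f"physician effect key {key!r} must be 'column=level'")
            if or_ <= 0:
                raise ValueError("physician effect odds ratios must be positive")
        for s in self.strata:
            worst = s.baseline_p * s.drift * max(self.true_rr, 1.0)
            if worst >= 1:
                raise ValueError(
                    f"stratum {s.name!r}: expected endline proportion "
                    f"{worst:.3f} outside (0,1)"
                )
        return self

    @property
    def eligible_fraction(self) -> float:
        return 1.0 - sum(self.ineligible_fractions.values())


def paper_preset(name: str) -> SimulationConfig:
    """Named study conditions.

    * ``four_province_trial`` — four provinces with baselines
      {4%, 49%, 72%, 77%}, 9 clusters/arm/stratum (72 hospitals), ~100
      screened prescriptions per cluster-period, k = 0.1, a modest
      intervention risk ratio of 1.12, realistic ineligible contamination
      (about a third of prescriptions lack ceftriaxone) and 10% record loss.
    * ``yunnan_low_baseline`` — a single very-low-baseline province (4%)
      where a 15-percentage-point absolute rise corresponds to RR 4.75.
    * ``null_trial`` — 2 moderate-adherence strata (30%, 45%), 9
      clusters/arm/stratum, ~100 prescriptions per cluster, k = 0.25,
      true RR 1; no contamination or loss, so the inference machinery is
      exercised in isolation.
    """
    contamination = {
        "under_18": 0.02,
        "pregnant_or_lactating": 0.03,
        "no_ceftriaxone": 0.33,
        "other_infection_antibiotics": 0.08,
        "complicated": 0.03,
    }
    if name == "four_province_trial":
        return SimulationConfig(
            strata=[
                StratumConfig(name="yunnan", baseline_p=0.04),
                StratumConfig(name="zhejiang", baseline_p=0.49),
                StratumConfig(name="guangdong", baseline_p=0.72),
                StratumConfig(name="hainan", baseline_p=0.77),
            ],
            clusters_per_arm_per_stratum=9,
            prescriptions_per_cluster=100,
            true_rr=1.12,
            k=0.1,
            ineligible_fractions=contamination,
            loss_fraction=0.10,
        )
    if name == "yunnan_low_baseline":
        return SimulationConfig(
            strata=[StratumConfig(name="yunnan", baseline_p=0.04)],
            clusters_per_arm_per_stratum=9,
            prescriptions_per_cluster=100,
            true_rr=4.75,
            k=0.1,
            ineligible_fractions=contamination,
            loss_fraction=0.10,
        )
    if name == "null_trial":
        return SimulationConfig(
            strata=[
                StratumConfig(name="stratum_a", baseline_p=0.30),
                StratumConfig(name="stratum_b", baseline_p=0.45),
            ],
            clusters_per_arm_per_stratum=9,
            prescriptions_per_cluster=100,
            true_rr=1.0,
            k=0.25,
        )
    raise ValidationError(f"unknown preset {name!r}")


def _cluster_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Latent per-(cluster, period) true proportions.

    One gamma multiplier per cluster (shared across periods); arm assigned
    by random permutation within stratum.
    """
    rows = []
    for s in config.strata:
        c = config.clusters_per_arm_per_stratum
        arms = np.array(["control"] * c + ["intervention"] * c)
        rng.shuffle(arms)
        if config.k > 0:
            shape = 1.0 / config.k**2
            g = rng.gamma(shape, 1.0 / shape, size=2 * c)
        else:
            g = np.ones(2 * c)
        for i, (arm, gi) in enumerate(zip(arms, g)):
            base = s.baseline_p * gi
            for period in ("baseline", "endline"):
                p = base
                if period == "endline":
                    p *= s.drift
                    if arm == "intervention":
                        p *= config.true_rr
                rows.append({
                    "cluster_id": f"{s.name}-{i:02d}",
                    "stratum": s.name,
                    "arm": arm,
                    "period": period,
                    "g": gi,
                    "p_true": min(max(p, EPS), 1 - EPS),
                    "clamped": not (EPS < p < 1 - EPS),
                })
    return pd.DataFrame(rows)


def generate_cluster_summaries(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: cluster-level summaries only, no record tables.

    Eligible denominators are Poisson with mean
    ``prescriptions_per_cluster * eligible_fraction * (1 - loss_fraction)``
    and events are binomial at the latent proportion (physician effects,
    which average out by construction, are not simulated on this path).
    Returns (summaries, truth) DataFrames.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = _cluster_truth(config, rng)
    mean_n = (config.prescriptions_per_cluster * config.eligible_fraction
              * (1 - config.loss_fraction))
    n = rng.poisson(mean_n, size=len(truth))
    o = rng.binomial(n, truth["p_true"].to_numpy())
    summaries = truth[["cluster_id", "stratum", "arm", "period"]].copy()
    summaries["o"] = o
    summaries["n"] = n
    summaries["p"] = np.where(n > 0, o / np.where(n > 0, n, 1), np.nan)
    summaries["flagged"] = n == 0
    return summaries, truth


def _draw_categorical(rng, freqs: dict[str, float], size: int) -> np.ndarray:
    levels = list(freqs)
    p = np.array([freqs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=size, p=p)]


def _physician_offsets(
    physicians: pd.DataFrame, effects: dict[str, float]
) -> tuple[np.ndarray, dict[str, float]]:
    """Adherence-scale logit offsets per physician, centred at expectation.

    Effects are odds ratios on *nonadherence*; the adherence-scale
    coefficient is the negated log OR.  Centring subtracts the population
    expectation of the offset (under PHYSICIAN_FREQS) so that an average
    physician leaves the cluster's latent proportion unchanged.
    """
    offsets = np.zeros(len(physicians))
    betas: dict[str, float] = {}
    expectation = 0.0
    for key, or_nonadh in effects.items():
        column, level = key.split("=", 1)
        if column not in physicians.columns:
            raise ValidationError(f"physician effect on unknown column {column!r}")
        beta = -math.log(or_nonadh)
        betas[key] = beta
        offsets += beta * (physicians[column].astype(str) == level).to_numpy()
        expectation += beta * PHYSICIAN_FREQS.get(column, {}).get(level, 0.0)
    return offsets - expectation, betas


def generate_physicians(
    config: SimulationConfig,
    cluster_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    m = config.physicians_per_cluster
    total = m * len(cluster_ids)
    df = pd.DataFrame({
        "physician_id": [f"p-{cid}-{j:02d}" for cid in cluster_ids for j in range(m)],
        "cluster_id": np.repeat(cluster_ids, m),
    })
    for column, freqs in PHYSICIAN_FREQS.items():
        df[column] = _draw_categorical(rng, freqs, total)
    df["prior_training"] = df["prior_training"] == "True"
    return df


def generate_trial(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full trial: prescription table, physician roster, truth record.

    Deterministic given ``config`` (including its seed): the same config
    yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth = _cluster_truth(config, rng)
    clusters = truth[["cluster_id", "stratum", "arm"]].drop_duplicates()
    cluster_ids = clusters["cluster_id"].tolist()
    physicians = generate_physicians(config, cluster_ids, rng)
    offsets, betas = _physician_offsets(physicians, config.physician_effects)

    # expand one row per screened prescription
    n_rx = rng.poisson(config.prescriptions_per_cluster, size=len(truth))
    base = truth.loc[truth.index.repeat(n_rx)].reset_index(drop=True)
    n_total = len(base)

    reasons = list(EXCLUSION_ORDER)
    probs = np.array([config.ineligible_fractions.get(r, 0.0) for r in reasons]
                     + [config.eligible_fraction])
    category = rng.choice(len(reasons) + 1, size=n_total, p=probs / probs.sum())
    eligible = category == len(reasons)

    phys_idx = rng.integers(0, config.physicians_per_cluster, size=n_total)
    cluster_pos = base["cluster_id"].map(
        {cid: i for i, cid in enumerate(cluster_ids)}
    ).to_numpy()
    flat_idx = cluster_pos * config.physicians_per_cluster + phys_idx
    physician_id = physicians["physician_id"].to_numpy()[flat_idx]

    eta = logit(base["p_true"].to_numpy()) + offsets[flat_idx]
    adherent = (rng.random(n_total) < expit(eta)) & eligible
    deviation = rng.integers(0, len(_DEVIATIONS), size=n_total)

    pregnant = category == reasons.index("pregnant_or_lactating")
    sex = np.where(rng.random(n_total) < 0.5, "female", "male")
    sex[pregnant] = "female"
    age = rng.integers(18, 70, size=n_total)
    age[category == reasons.index("under_18")] = rng.integers(
        10, 18, size=int((category == reasons.index("under_18")).sum())
    )
    diagnosis = np.where(
        category == reasons.index("complicated"),
        "complicated_gonorrhea", "uncomplicated_gonorrhea",
    )

    drugs = np.empty(n_total, dtype=object)
    drugs[eligible & adherent] = _ADHERENT_DRUGS
    nonadh = eligible & ~adherent
    drugs[nonadh] = np.array(_DEVIATIONS, dtype=object)[deviation[nonadh]]
    for ri, reason in enumerate(reasons):
        drugs[category == ri] = _INELIGIBLE_DRUGS[reason]

    prescriptions = pd.DataFrame({
        "record_id": [f"r{i:07d}" for i in range(n_total)],
        "cluster_id": base["cluster_id"],
        "stratum": base["stratum"],
        "arm": base["arm"],
        "period": base["period"],
        "patient_age": age,
        "patient_sex": sex,
        "pregnant_or_lactating": pregnant,
        "diagnosis": diagnosis,
        "drugs": drugs,
        "physician_id": physician_id,
    })
    if config.loss_fraction > 0:
        prescriptions = corrupt_records(
            prescriptions, config.loss_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    ge = truth[truth["period"] == "endline"]
    gm = ge.groupby("arm")["p_true"].apply(lambda p: float(np.exp(np.log(p).mean())))
    truth_record = {
        "config": config.model_dump(),
        "true_rr": config.true_rr,
        "latent_gm_rr_endline": gm["intervention"] / gm["control"],
        "n_clamped": int(truth["clamped"].sum()),
        "physician_beta_adherence": betas,
        "physician_or_nonadherence": dict(config.physician_effects),
        "clusters": truth.to_dict(orient="records"),
    }
    return prescriptions, physicians, truth_record


def corrupt_records(
    prescriptions: pd.DataFrame, loss_fraction: float, seed: int
) -> pd.DataFrame:
    """Blank a required field in a ``loss_fraction`` share of records.

    Emulates illegible prescriptions: corrupted rows fail downstream
    validation and are counted in the flow report.  The number corrupted is
    ``round(loss_fraction * len)``.
    """
    if not 0 <= loss_fraction < 1:
        raise ValidationError("loss_fraction must be in [0,1)")
    df = prescriptions.copy()
    n_corrupt = round(loss_fraction * len(df))
    if n_corrupt == 0:
        return df
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(df), size=n_corrupt, replace=False)
    # blank only fields whose absence fails validation (an empty drugs list
    # is a legal record, so it is not a corruption target)
    fields = np.array(["patient_age", "diagnosis", "patient_sex", "period"], dtype=object)
    which = rng.integers(0, len(fields), size=n_corrupt)
    for f in np.unique(which):
        col = fields[f]
        df[col] = df[col].astype(object)
        df.loc[df.index[rows[which == f]], col] = ""
    return df
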