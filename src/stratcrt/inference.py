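"""Cluster-level summary inference for stratified cluster-randomized trials.

The estimand on the ratio scale is the ratio of geometric mean cluster
risks between arms.  Per cluster i we form the adherence proportion
p_i = o_i/n_i, log-transform it (with a continuity substitution
(o+0.5)/(n+1) when o_i is 0 or n_i, since log 0 is undefined), and within
each stratum j take

    effect_j = mean(log p, intervention) - mean(log p, control)
    v_j      = s2 * (1/c1j + 1/c0j)

with s2 the within-arm sample variance of cluster log-risks pooled over
all strata and arms (sums of squares about the arm means divided by
sum_j (c1j + c0j - 2)).  Strata are combined with inverse-variance weights
(model-based: a separate variance estimate per stratum on few clusters
makes the weighted t anticonservative), SE = sqrt(1 / sum 1/v_j), and
inference uses a t reference with df = sum_j (c1j + c0j - 2).  The
risk-difference analysis runs the identical machinery on the untransformed
proportions.

Covariate adjustment follows the ratio-residual approach: a logistic model
is fitted to individual-level outcomes with terms for the covariates of
interest but *excluding* the treatment arm; each cluster's expected event
count e_i is the sum of fitted probabilities over its individuals, and the
cluster-level analysis is rerun on the ratio residuals r_i = o_i/e_i (log
scale) or difference residuals d_i = (o_i - e_i)/n_i.  With an
intercept-only model both reduce exactly to the unadjusted analysis, which
serves as a built-in identity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import (
    ComputationError,
    DegenerateWeightError,
    RankDeficiencyError,
    SeparationError,
    SmallStratumError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["cluster_id", "stratum", "arm", "period", "o", "n"]


@dataclass(frozen=True)
class StratumEstimate:
    stratum: str
    c1: int                 # intervention clusters
    c0: int                 # control clusters
    effect: float           # log RR or RD
    variance: float
    weight: float           # normalized inverse-variance weight


@dataclass(frozen=True)
class EffectEstimate:
    scale: str              # "ratio" | "difference"
    point: float
    se: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float
    adjusted: bool = False
    covariates: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class CovariateModel:
    """Maximum-likelihood logistic fit (IRLS) without a treatment term."""

    terms: list[str]
    coefficients: np.ndarray
    fitted: np.ndarray
    iterations: int
    max_score: float
    converged: bool

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


def continuity_adjusted_p(o, n):
    """p with the (o+0.5)/(n+1) substitution at o = 0 or o = n."""
    o = np.asarray(o, dtype=float)
    n = np.asarray(n, dtype=float)
    boundary = (o == 0) | (o == n)
    return np.where(boundary, (o + 0.5) / (n + 1.0), o / np.where(n > 0, n, np.nan))


def log_cluster_risks(
    summaries: pd.DataFrame, use_residuals: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Attach the log cluster risk (or log ratio residual) to each summary row.

    Clusters with n = 0 are dropped with a logged warning; the returned
    metadata counts drops and boundary continuity substitutions.
    """
    df = summaries.copy()
    dropped = int((df["n"] == 0).sum())
    if dropped:
        logger.warning("dropping %d cluster summaries with n=0", dropped)
        df = df[df["n"] > 0].copy()
    boundary = int(((df["o"] == 0) | (df["o"] == df["n"])).sum())
    p_tilde = continuity_adjusted_p(df["o"], df["n"])
    if use_residuals:
        if "e" not in df or df["e"].isna().any():
            raise ValidationError("use_residuals requires residualized summaries ('e')")
        # r_i = p_tilde * n / e: the continuity substitution is applied to the
        # numerator so log r is defined for zero-event clusters and the
        # intercept-only identity with the unadjusted analysis is exact.
        df["log_risk"] = np.log(p_tilde * df["n"].to_numpy() / df["e"].to_numpy())
    else:
        df["log_risk"] = np.log(p_tilde)
    meta = {"dropped_zero_n": dropped, "continuity_substitutions": boundary}
    return df, meta


def _check_arms(df: pd.DataFrame):
    present = set(df["arm"].unique())
    if present != {"control", "intervention"}:
        raise ValidationError(f"need both arms present, got {sorted(present)}")


def _stratified_estimate(
    df: pd.DataFrame,
    value_col: str,
    scale: str,
    alpha: float,
    adjusted: bool,
    covariates: tuple[str, ...],
    small_stratum: str,
) -> tuple[EffectEstimate, list[StratumEstimate]]:
    _check_arms(df)
    if small_stratum not in ("error", "merge_smallest"):
        raise ValidationError(f"unknown small_stratum policy {small_stratum!r}")
    df = df.copy()
    df["_stratum"] = df["stratum"].astype(str)
    df = _merge_small_strata(df, small_stratum)

    # Pooled within-stratum, within-arm sample variance: sums of squares
    # about the arm means are pooled across strata and arms onto
    # sum_j (c1j + c0j - 2) df, then v_j = s2 * (1/c1j + 1/c0j).  Pooling
    # (rather than estimating a separate variance per stratum) keeps the
    # inverse-variance weights model-based; per-stratum variance estimates
    # on few clusters make the weighted t-test anticonservative.
    names, effects, c1s, c0s = [], [], [], []
    ss_total, df_total = 0.0, 0
    for stratum, g in df.groupby("_stratum", sort=True):
        y1 = g.loc[g["arm"] == "intervention", value_col].to_numpy(dtype=float)
        y0 = g.loc[g["arm"] == "control", value_col].to_numpy(dtype=float)
        c1, c0 = len(y1), len(y0)
        if c1 < 2 or c0 < 2:
            raise SmallStratumError(
                f"stratum {stratum!r} has <2 clusters in an arm (c1={c1}, c0={c0})"
            )
        names.append(str(stratum))
        effects.append(float(y1.mean() - y0.mean()))
        c1s.append(c1)
        c0s.append(c0)
        ss_total += float(((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum())
        df_total += c1 + c0 - 2
    s2 = ss_total / df_total
    if s2 == 0:
        raise DegenerateWeightError(
            "zero between-cluster variance in every stratum; weights undefined"
        )
    variances = [s2 * (1 / c1 + 1 / c0) for c1, c0 in zip(c1s, c0s)]
    strata = [
        StratumEstimate(nm, c1, c0, eff, v, 0.0)
        for nm, c1, c0, eff, v in zip(names, c1s, c0s, effects, variances)
    ]
    inv = np.array([1 / s.variance for s in strata])
    weights = inv / inv.sum()
    strata = [
        StratumEstimate(s.stratum, s.c1, s.c0, s.effect, s.variance, float(w))
        for s, w in zip(strata, weights)
    ]
    point_lin = float(sum(s.weight * s.effect for s in strata))
    se = float(math.sqrt(1.0 / inv.sum()))
    dof = int(sum(s.c1 + s.c0 - 2 for s in strata))
    t_stat = point_lin / se
    p = float(2 * stats.t.sf(abs(t_stat), dof))
    t_crit = float(stats.t.ppf(1 - alpha / 2, dof))
    lo, hi = point_lin - t_crit * se, point_lin + t_crit * se
    if scale == "ratio":
        est = EffectEstimate("ratio", math.exp(point_lin), se, math.exp(lo),
                             math.exp(hi), t_stat, dof, p, adjusted, covariates)
    else:
        est = EffectEstimate("difference", point_lin, se, lo, hi, t_stat, dof, p,
                             adjusted, covariates)
    return est, strata


def _merge_small_strata(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Optionally merge strata with <2 clusters in an arm into the smallest neighbor."""
    if policy != "merge_smallest":
        return df
    while True:
        sizes = df.groupby(["_stratum", "arm"])["cluster_id"].count().unstack(fill_value=0)
        if sizes.shape[1] < 2:
            break
        small = sizes[(sizes < 2).any(axis=1)].index.tolist()
        if not small or len(sizes) == 1:
            break
        victim = small[0]
        others = df.loc[df["_stratum"] != victim].groupby("_stratum")["cluster_id"].count()
        target = others.idxmin()
        logger.warning("merging small stratum %r into %r", victim, target)
        df.loc[df["_stratum"] == victim, "_stratum"] = target
    return df


def stratified_risk_ratio(
    summaries: pd.DataFrame,
    use_residuals: bool = False,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = (),
    small_stratum: str = "error",
) -> tuple[EffectEstimate, list[StratumEstimate]]:
    """Stratified ratio of geometric mean cluster risks, intervention vs control."""
    df, _ = log_cluster_risks(summaries, use_residuals=use_residuals)
    return _stratified_estimate(
        df, "log_risk", "ratio", alpha, use_residuals, covariates, small_stratum
    )


def stratified_risk_difference(
    summaries: pd.DataFrame,
    use_residuals: bool = False,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = (),
    small_stratum: str = "error",
) -> tuple[EffectEstimate, list[StratumEstimate]]:
    """Stratified difference of mean cluster risks (or difference residuals)."""
    df = summaries.copy()
    dropped = int((df["n"] == 0).sum())
    if dropped:
        logger.warning("dropping %d cluster summaries with n=0", dropped)
        df = df[df["n"] > 0].copy()
    if use_residuals:
        if "d" not in df or df["d"].isna().any():
            raise ValidationError("use_residuals requires residualized summaries ('d')")
        df["_value"] = df["d"].astype(float)
    else:
        df["_value"] = df["o"].astype(float) / df["n"].astype(float)
    return _stratified_estimate(
        df, "_value", "difference", alpha, use_residuals, covariates, small_stratum
    )


# ---------------------------------------------------------------------------
# individual-level covariate model (IRLS logistic, no treatment term)

def fit_covariate_model(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    terms: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CovariateModel:
    """Fit a logistic regression by iteratively reweighted least squares.

    ``X`` is the encoded design matrix (reference-level dummies already
    applied); an intercept column is prepended unless ``add_intercept`` is
    False.  Convergence requires max |score| < ``tol`` within ``max_iter``
    iterations.  Rank deficiency raises naming the aliased terms; apparent
    separation (non-convergence with a coefficient beyond +-15) raises
    naming the diverging term.
    """
    if isinstance(X, pd.DataFrame):
        terms = terms or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        terms = terms or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        terms = ["intercept"] + list(terms)
    n, p = X.shape
    if len(y) != n:
        raise ValidationError("X and y length mismatch")

    # rank check via pivoted QR: small trailing diagonal -> aliased columns
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    if diag.size and (diag < 1e-10 * max(diag[0], 1.0)).any():
        aliased = [terms[piv[j]] for j in range(len(diag))
                   if diag[j] < 1e-10 * max(diag[0], 1.0)]
        raise RankDeficiencyError(aliased)

    beta = np.zeros(p)
    max_score = np.inf
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        max_score = float(np.max(np.abs(score)))
        if max_score < tol:
            # under perfect separation the score also vanishes, but only
            # because coefficients have diverged; a converged fit with a
            # coefficient beyond +-15 on any reasonable covariate scale is
            # separation, not signal
            big = int(np.argmax(np.abs(beta)))
            if abs(beta[big]) > 15:
                raise SeparationError(terms[big], float(beta[big]))
            return CovariateModel(list(terms), beta, expit(X @ beta), it, max_score, True)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise ComputationError(f"IRLS normal equations singular: {exc}") from exc
        beta = beta + delta
    big = int(np.argmax(np.abs(beta)))
    if abs(beta[big]) > 15:
        raise SeparationError(terms[big], float(beta[big]))
    raise ComputationError(
        f"logistic fit did not converge in {max_iter} iterations (max score {max_score:.3g})"
    )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def build_design_matrix(
    individuals: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Reference-level dummy encoding of the requested covariate columns.

    Categorical (object/category) columns are expanded with the first
    sorted level as reference; numeric columns pass through.  Term names
    are ``column=level`` for dummies.
    """
    pieces = []
    for cov in covariates:
        if cov not in individuals:
            raise ValidationError(f"covariate column {cov!r} missing from individuals")
        col = individuals[cov]
        if col.dtype.kind in "ifu":
            pieces.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                pieces.append(
                    (col.astype(str) == level).astype(float).rename(f"{cov}={level}")
                )
    if not pieces:
        return pd.DataFrame(index=individuals.index)
    return pd.concat(pieces, axis=1)


def residualize(
    summaries: pd.DataFrame,
    model: CovariateModel,
    individuals: pd.DataFrame,
) -> pd.DataFrame:
    """Fill e (predicted events), r (ratio residual) and d (difference residual).

    ``individuals`` must be the same endline rows the model was fitted on,
    carrying ``cluster_id``; e_i sums the fitted probabilities per cluster,
    so sum(e) = sum(o) by the intercept score equation.
    """
    if len(individuals) != len(model.fitted):
        raise ValidationError("individuals and fitted probabilities length mismatch")
    pred = individuals.assign(_fitted=model.fitted).groupby("cluster_id")["_fitted"].sum()
    df = summaries.copy()
    df["e"] = df["cluster_id"].map(pred)
    if df["e"].isna().any():
        missing = df.loc[df["e"].isna(), "cluster_id"].tolist()
        raise ValidationError(f"no individuals for clusters {missing[:5]}")
    if (df["e"] <= 0).any():
        raise ComputationError("non-positive predicted event count")
    p_tilde = continuity_adjusted_p(df["o"], df["n"])
    df["r"] = p_tilde * df["n"].to_numpy() / df["e"].to_numpy()
    df["d"] = (df["o"] - df["e"]) / df["n"]
    return df


@dataclass(frozen=True)
class PairedChangeResult:
    arm: str
    n_clusters: int
    mean_difference: float
    se: float
    ci_low: float
    ci_high: float
    t_stat: float | None
    df: int
    p_value: float | None
    zero_variance: bool = False


def paired_change_test(
    summaries: pd.DataFrame, arm: str, alpha: float = 0.05
) -> PairedChangeResult:
    """Paired t-test of per-cluster endline-minus-baseline proportion changes.

    Uses clusters of ``arm`` with nonzero denominators in both periods.
    Zero-variance differences are reported with the p-value undefined.
    """
    g = summaries[(summaries["arm"] == arm) & (summaries["n"] > 0)]
    wide = g.pivot_table(index="cluster_id", columns="period", values="p")
    wide = wide.dropna(subset=["baseline", "endline"])
    if len(wide) < 2:
        raise ValidationError(f"arm {arm!r}: need >=2 clusters with both periods")
    diff = (wide["endline"] - wide["baseline"]).to_numpy(dtype=float)
    c = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    dof = c - 1
    if sd == 0:
        return PairedChangeResult(arm, c, mean, 0.0, mean, mean, None, dof, None, True)
    se = sd / math.sqrt(c)
    t_stat = mean / se
    t_crit = float(stats.t.ppf(1 - alpha / 2, dof))
    return PairedChangeResult(
        arm, c, mean, se, mean - t_crit * se, mean + t_crit * se,
        float(t_stat), dof, float(2 * stats.t.sf(abs(t_stat), dof)), False,
    )
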