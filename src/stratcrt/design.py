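"""Design of cluster-randomized trials with binary outcomes.

Sample size uses the unmatched cluster-randomized formula in which
between-cluster heterogeneity enters through k, the coefficient of
variation of true cluster-level proportions (SD of true proportions over
their mean, assumed common to both arms).  With n individuals observed per
cluster (after data loss) and true proportions pi0, pi1, the number of
clusters per arm is

    c = 1 + (z_{a/2} + z_b)^2 [pi0(1-pi0)/n + pi1(1-pi1)/n
                               + k^2 (pi0^2 + pi1^2)] / (pi0 - pi1)^2

rounded up.  The leading "+1" compensates for estimating between-cluster
variance from few clusters (and absorbs the df cost of stratification).
Standard-normal quantiles are used throughout, per the convention for this
formula; the +1 term stands in for the small-df correction.

Stratified sizing is exposed as a mode flag: ``per_stratum=True`` treats c
as the requirement per stratum (total 2 * c * n_strata), matching designs
that set a fixed per-province allocation target, otherwise the total is
2 * c pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NoDetectableEffectError, ValidationError


@dataclass(frozen=True)
class DesignSpec:
    """Assumptions for a two-arm 1:1 stratified cluster-randomized design.

    pi0/pi1 are the true outcome proportions in control/intervention
    clusters, n_per_cluster the expected individuals per cluster before
    loss, k the between-cluster coefficient of variation of true
    proportions, loss_fraction the anticipated share of unusable
    individual records.
    """

    pi0: float
    pi1: float
    n_per_cluster: float
    k: float = 0.0
    alpha: float = 0.05
    power: float = 0.90
    loss_fraction: float = 0.0
    n_strata: int = 1

    def __post_init__(self):
        for name in ("pi0", "pi1"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.n_per_cluster <= 0:
            raise ValidationError("n_per_cluster must be positive")
        if self.k < 0:
            raise ValidationError("k must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0,1)")
        if not 0 <= self.loss_fraction < 1:
            raise ValidationError("loss_fraction must be in [0,1)")
        if self.n_strata < 1:
            raise ValidationError("n_strata must be >= 1")

    @property
    def effective_n(self) -> float:
        """Usable individuals per cluster after record loss."""
        return self.n_per_cluster * (1 - self.loss_fraction)


@dataclass(frozen=True)
class DesignResult:
    clusters_per_arm: int
    total_clusters: int
    achieved_power: float
    effective_n: float


def _variance_term(spec: DesignSpec) -> float:
    n = spec.effective_n
    return (
        spec.pi0 * (1 - spec.pi0) / n
        + spec.pi1 * (1 - spec.pi1) / n
        + spec.k**2 * (spec.pi0**2 + spec.pi1**2)
    )


def clusters_required(spec: DesignSpec, per_stratum: bool = False) -> DesignResult:
    """Clusters per arm needed to detect pi1 vs pi0 at the spec's power.

    With ``per_stratum`` the returned ``clusters_per_arm`` is the per-stratum
    requirement and ``total_clusters`` multiplies across strata.
    """
    if spec.pi1 == spec.pi0:
        raise NoDetectableEffectError("pi1 == pi0: no effect to detect")
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    c_exact = 1 + (z_a + z_b) ** 2 * _variance_term(spec) / (spec.pi1 - spec.pi0) ** 2
    c = max(2, math.ceil(c_exact))
    total = 2 * c * (spec.n_strata if per_stratum else 1)
    return DesignResult(
        clusters_per_arm=c,
        total_clusters=total,
        achieved_power=power_given_clusters(spec, c),
        effective_n=spec.effective_n,
    )


def power_given_clusters(spec: DesignSpec, clusters_per_arm: int) -> float:
    """Power of the design at a fixed number of clusters per arm.

    Inverts the sample-size identity for z_beta, so it round-trips with
    :func:`clusters_required`.
    """
    if clusters_per_arm < 2:
        raise ValidationError("clusters_per_arm must be >= 2")
    if spec.pi1 == spec.pi0:
        raise NoDetectableEffectError("pi1 == pi0: no effect to detect")
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_sum = math.sqrt(
        (clusters_per_arm - 1) * (spec.pi1 - spec.pi0) ** 2 / _variance_term(spec)
    )
    return float(stats.norm.cdf(z_sum - z_a))


@dataclass
class SealedAllocation:
    """Arm assignment generated now, disclosed later.

    Randomization and disclosure are deliberately separate calls so that
    allocation concealment is representable: the object can be created,
    stored, and only ``reveal()``-ed at assignment time.
    """

    seed: int
    _assignment: dict[str, str] = field(repr=False, default_factory=dict)
    revealed: bool = field(default=False)

    def reveal(self) -> dict[str, str]:
        self.revealed = True
        return dict(self._assignment)

    def split_sizes(self) -> dict[str, int]:
        """Arm counts only; safe to inspect without unblinding."""
        out: dict[str, int] = {}
        for armname in self._assignment.values():
            out[armname] = out.get(armname, 0) + 1
        return out


def allocate(
    clusters_by_stratum: dict[str, list[str]],
    seed: int,
    remainder: str = "error",
) -> SealedAllocation:
    """1:1 stratified randomization of clusters to arms.

    Within each stratum exactly half the clusters go to each arm (a
    computer-generated permutation, deterministic given ``seed``).  Odd
    strata follow ``remainder``: ``"error"`` (default), ``"extra_to_control"``
    or ``"extra_to_intervention"``.
    """
    if remainder not in ("error", "extra_to_control", "extra_to_intervention"):
        raise ValidationError(f"unknown remainder rule {remainder!r}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for stratum in sorted(clusters_by_stratum):
        ids = list(clusters_by_stratum[stratum])
        if not ids:
            raise ValidationError(f"stratum {stratum!r} has no clusters")
        if len(ids) % 2 and remainder == "error":
            raise ValidationError(
                f"stratum {stratum!r} has an odd cluster count ({len(ids)}) "
                "and no remainder rule"
            )
        order = rng.permutation(len(ids))
        n_intervention = len(ids) // 2
        if len(ids) % 2 and remainder == "extra_to_intervention":
            n_intervention += 1
        for rank, idx in enumerate(order):
            arm = "intervention" if rank < n_intervention else "control"
            assignment[ids[idx]] = arm
    return SealedAllocation(seed=seed, _assignment=assignment)
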