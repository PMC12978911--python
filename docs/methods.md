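# Methods

## Scope and data model

The package analyses two-arm, 1:1, stratified cluster-randomized trials with
a binary individual-level outcome aggregated to cluster proportions. The
motivating application is physician adherence to a gonorrhea treatment
guideline: one record per dispensed prescription, hospitals as clusters,
provinces as strata, two observation periods (baseline and endline) per
cluster. Records carry patient demographics, diagnosis, the drug orders
(name, dose, route, number of administrations, indication) and a physician
identifier linking to a roster of physician covariates.

## Eligibility and adjudication

Five exclusion criteria are applied in a fixed order — patient under 18,
pregnant/lactating, no ceftriaxone order, antibiotics for other infections,
complicated gonorrhea — and the first matching criterion is the *primary*
reason used in flow tallies (all matching reasons are stored on the
decision). The order is a reporting convention only; eligibility itself is
order-independent. Screening is idempotent by construction.

Adherence is a deterministic rule: exactly one ceftriaxone order, one
administration of 1000 mg by the intramuscular route, and no additional
gonorrhea-indicated antibiotic. Two edge cases are resolved explicitly:
a missing route is a deviation (the guideline regimen specifies IM), logged
as a warning; a correct ceftriaxone regimen plus an extra gonorrhea-indicated
antibiotic is called nonadherent **and flagged ambiguous**, because guideline
text typically does not address combination prescribing — the flag surfaces
these for human review instead of hiding the judgement. Dual review is
modelled as an optional per-record override: disagreements with the rule
engine are flagged, never silently resolved.

Drug names are matched case-insensitively against a configurable synonym
list (generic name plus common trade names), since hospital information
systems are inconsistent about naming.

## Cluster-level inference

Cluster proportions under ~10–20 clusters per arm are analysed at the
cluster level; this is robust to within-cluster correlation without
modelling it. Log-transformed proportions deal with the skewness of
proportions across heterogeneous clusters, and the arm contrast of mean log
risks is the log of the **ratio of geometric mean risks**.

Choices the generic description leaves open, and how they are fixed here:

* **Continuity**: clusters with 0 or n events use (o+0.5)/(n+1) before the
  log; substitutions are counted in the output. Clusters with n = 0 are
  dropped with a logged count.
* **Variance and weights**: the within-arm sums of squares of cluster
  log-risks are pooled over all strata and arms onto Σ(c1j+c0j−2) degrees of
  freedom, giving v_j = s²(1/c1j+1/c0j) and weights w_j ∝ 1/v_j. Pooling
  makes the weights model-based (proportional to harmonic cluster counts).
  The alternative — estimating a separate variance per stratum and weighting
  by its inverse — was evaluated by simulation and is anticonservative with
  few clusters per stratum (rejection rate ≈ 0.067 at nominal 0.05 under the
  null generator; the pooled form is ≈ 0.053, inside the Monte-Carlo band;
  see `tests/test_acceptance.py`), because each estimated precision 1/v̂_j is
  biased upward and correlates with the stratum effect. Pooling assumes a
  common within-arm variance of log risks across strata; with equal cluster
  counts per stratum the test is robust to moderate violations (verified by
  a heteroscedastic-strata simulation during development).
* **Degrees of freedom**: Σ_j (c1j + c0j − 2) — two arm means estimated per
  stratum.
* **Strata with <2 clusters in an arm**: hard error by default; an explicit
  `merge_smallest` policy folds such strata into the smallest neighbour
  (merging changes the estimand, so it is never silent).
* The risk-difference analysis is the identical machinery on untransformed
  proportions; no continuity substitution is needed there.

## Covariate adjustment by ratio residuals

A logistic model is fitted to individual outcomes with terms for the
covariates of interest and **no treatment term**; each cluster's expected
event count e_i is the sum of fitted probabilities, and the cluster analysis
reruns on ratio residuals r_i (log scale) or difference residuals
d_i = (o_i − e_i)/n_i. Because the intercept score equation forces
Σe_i = Σo_i, an intercept-only model yields r_i = p_i/p̄ and the adjusted
estimate reproduces the unadjusted one exactly on both scales — a built-in
identity the tests assert at 1e-10.

One refinement: r_i is computed as p̃_i·n_i/e_i with the same continuity
substitution p̃ used on the unadjusted scale, so that log r_i is defined for
zero-event clusters and the intercept-only identity is exact including
boundary clusters.

Default adjustment covariates: stratum, cluster-level baseline adherence
proportion (entered as a cluster-constant numeric covariate), patient sex,
patient age in years (numeric, unbanded), physician sex and department.

The fit is plain maximum likelihood via iteratively reweighted least
squares: convergence at max |score| < 1e-8 within 50 iterations; pivoted-QR
rank screening names aliased terms; a diverged coefficient (|β| > 15) —
whether the score loop stalls or "converges" because fitted probabilities
have saturated — raises a separation error naming the term. The
implementation is cross-checked against statsmodels in the test suite.

## Within-arm change

Per arm, a classical paired t-test on per-cluster (endline − baseline)
proportions, df = clusters − 1. Zero-variance differences are reported with
an explicit flag and an undefined p-value rather than a fabricated one.

## Design calculations

Clusters per arm: c = 1 + (z_{α/2}+z_β)² [π₀(1−π₀)/n + π₁(1−π₁)/n +
k²(π₀²+π₁²)] / (π₀−π₁)², with n the post-loss individuals per cluster
(loss applies to records, not clusters, because loss arises from illegible
prescriptions) and k the coefficient of variation of true cluster
proportions. Standard-normal quantiles are used; the leading +1 compensates
for estimating the between-cluster variance from few clusters. At k = 0 the
formula reduces to the classical two-proportion sample size divided by
cluster size, plus one cluster. Power inversion solves the same identity for
z_β, so sizing and power round-trip. Stratified sizing is a mode flag
(per-stratum vs pooled) because fixed per-stratum allocation targets are a
design policy, not a formula output.

Randomization is a seeded permutation within each stratum, exactly half per
arm (odd strata need an explicit remainder rule). Generation and disclosure
are separate calls so allocation concealment is representable.

## Synthetic-trial generator

What it emulates:

* **Strata**: province-like baselines spanning the realistic 4%–77% range.
* **Between-cluster heterogeneity**: a multiplicative gamma effect on the
  risk scale with mean 1 and CV k — matching how k is defined in the
  sample-size tradition (CV of *true proportions*, not log-odds). The effect
  is shared by a cluster's two periods, so baseline adherence is a genuinely
  informative covariate. Proportions are clamped to [1e-4, 1−1e-4]; clamp
  events are counted in the truth record.
* **Intervention effect**: multiplies risk at endline in intervention
  clusters — exactly the geometric-mean risk-ratio estimand.
* **Physician effects**: odds ratios on *nonadherence* (the scale on which
  physician-factor tables report them, e.g. OR ≈ 2.6 for age < 35, ≈ 4 for
  dermatology). They enter each prescription's adherence logit as a negated
  log-OR offset, centred by its expectation under the roster frequencies so
  that an average physician leaves the cluster's latent proportion — and
  hence the estimand — unchanged. Risk-scale cluster effects and odds-scale
  physician effects deliberately coexist; the truth record stores both.
* **Contamination**: each screened record is ineligible for one configured
  reason with the configured probability, with the attributes that trigger
  that reason (about a third of real prescriptions lack ceftriaxone, so the
  default contamination makes roughly half of records eligible, matching
  published flow percentages in the 36%–52% range).
* **Illegibility**: `corrupt_records` blanks a required field in a stated
  fraction of rows; these fail validation downstream and are counted before
  screening.

Named presets fix study conditions: `four_province_trial` (baselines
{0.04, 0.49, 0.72, 0.77}, 9 clusters/arm/stratum, ~100 prescriptions per
cluster-period, k = 0.1, RR 1.12, contamination and 10% loss),
`yunnan_low_baseline` (single 4% stratum, RR 4.75 ≙ a 15-point absolute
rise), and `null_trial` (two moderate strata 0.30/0.45, k = 0.25, RR 1, no
contamination — chosen so Monte-Carlo calibration exercises the inference
machinery in isolation at ~100 eligible prescriptions per cluster).

What it does **not** emulate: within-physician correlation of prescriptions
(each record is independent given cluster and physician effects; an explicit
random-effect extension was considered and left out of the default),
seasonal case-mix, multi-drug free-text prescriptions, or any feature of the
real confidential hospital data. Passing tests therefore demonstrate
correctness of the machinery under the stated generative assumptions, not
claims about any real trial's estimates.

## Numerical conventions and problem sizes

Percentages print with half-away-from-zero rounding (48.163…→48.2;
84.375→84.4), dropping a trailing ".0" at one decimal (41.97…→"42%"). 2×2
odds ratios use the Woolf log-scale CI with the Haldane–Anscombe 0.5
correction on all four cells when any cell is zero; tables with a zero
margin are rejected as degenerate. All randomness flows through explicit
`numpy.random.default_rng` seeds; identical configuration yields
byte-identical outputs.

Monte-Carlo checks in the test suite use 2000 null trials (type-I error),
500 trials for estimand recovery, 100 trials for the adjustment identity,
and 2000 clusters/arm for generator-convergence checks, via the generator's
cluster-summary fast path; the acceptance script uses 1000/500/20 replicates
for the corresponding quantities. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands (e.g. ±0.0049 on a 0.05
rejection rate at 2000 replicates).

## Known limitations

* The stratified t-test assumes approximately normal, homoscedastic cluster
  log-risks within arms after pooling; extreme heteroscedasticity across
  strata combined with unequal cluster counts would misweight strata.
* Ratio-residual adjustment ignores uncertainty in the fitted covariate
  model (standard for this two-stage approach).
* The logistic model excludes cluster random effects; with strong
  between-cluster variation its coefficient estimates are marginally
  attenuated, which is immaterial for residual construction but matters if
  the coefficients themselves are of interest.
* GEE/mixed-model individual-level alternatives, matched-pair designs,
  unequal allocation, and non-binary outcomes are out of scope.
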