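# stratcrt

Analysis, design, and simulation toolkit for **stratified cluster-randomized
trials (CRTs) of physician guideline adherence**, built around the motivating
case of antibiotic prescribing for uncomplicated gonorrhea: the national
guideline regimen is a single 1 g intramuscular dose of ceftriaxone, hospitals
(clusters) are randomized within province strata to a training intervention or
control, and the outcome is the proportion of prescriptions adherent to the
guideline.

It is written for trial statisticians and epidemiologists who need the
cluster-level summary methods appropriate when there are relatively few
clusters per arm: prescription eligibility screening and adherence
adjudication, stratified geometric-mean risk ratios and risk differences with
ratio-residual covariate adjustment, CV-based sample-size calculations, and a
synthetic-trial generator so the full pipeline is testable without access to
confidential hospital records.

## The statistical model

Let cluster *i* in stratum *j* contribute an adherence proportion
*p&#x2091;* = *o&#x2091;*/*n&#x2091;*. The ratio-scale estimand is the ratio
of **geometric mean cluster risks** between arms. Per stratum *j*:

    effect_j = mean(log p, intervention) − mean(log p, control)
    v_j      = s² (1/c1j + 1/c0j)

where *s*² is the within-arm sample variance of cluster log-risks pooled over
all strata and arms, and *c1j*, *c0j* are cluster counts per arm. Strata are
combined with inverse-variance weights *w_j* ∝ 1/*v_j*, the standard error is
√(1/Σ 1/*v_j*), and the test is a stratified two-tailed *t* with
df = Σ_j (*c1j* + *c0j* − 2). Zero- or full-event clusters use the continuity
substitution (*o*+0.5)/(*n*+1). The risk-difference analysis applies the same
machinery to untransformed proportions.

Covariate adjustment is by **ratio residuals**: a logistic model is fitted to
individual prescriptions with terms for stratum, cluster-level baseline
adherence, patient sex and age, and physician sex and department — *excluding*
the treatment arm — and the cluster analysis is rerun on
*r&#x2091;* = *o&#x2091;*/*e&#x2091;*, where *e&#x2091;* is the model-predicted
adherent count.

Sample size uses the unmatched CRT formula with between-cluster coefficient of
variation *k* (clusters per arm
= 1 + (z<sub>α/2</sub>+z<sub>β</sub>)²[π₀(1−π₀)/n + π₁(1−π₁)/n +
k²(π₀²+π₁²)]/(π₀−π₁)²). Note that a published design target of 144 clusters in
such trials reflects per-stratum allocation goals (e.g. 8 provinces × 18
hospitals), not a single pooled formula output; this module exposes both
per-stratum and pooled sizing modes and does not claim to reproduce any
particular target.

## Worked example

Simulate a four-province trial (baseline adherence 4%–77% across strata, nine
hospitals per arm per province, k = 0.1, a true risk ratio of 1.12, realistic
ineligible-record contamination and 10% illegible records), then run the full
primary analysis:

```sh
stratcrt simulate --preset four_province_trial --seed 42 --out-dir demo
stratcrt analyze --prescriptions demo/prescriptions.csv \
                 --physicians demo/physicians.csv --out-dir demo/out
```

which prints:

```
Adherence rates (eligible prescriptions):
  control/baseline: 812/1645 (49.4%)
  control/endline: 805/1648 (48.8%)
  intervention/baseline: 821/1663 (49.4%)
  intervention/endline: 919/1596 (57.6%)

Effect estimates (endline, intervention vs control):
  rr_unadjusted: RR 1.19 (95% CI 0.98 to 1.44; t=1.78, df=64, P=0.08)
  rr_adjusted: RR 1.20 (95% CI 0.98 to 1.46; t=1.84, df=64, P=0.07)
  rd_unadjusted: RD 7.1% (95% CI 2.9% to 11.2%; t=3.39, df=64, P=0.00)
  rd_adjusted: RD 7.3% (95% CI 3.5% to 11.1%; t=3.86, df=64, P=0.00)

Within-arm change, endline - baseline (paired t):
  control: mean difference -0.2% (95% CI -3.0% to 2.7%; P=0.90, paired t, df=35)
  intervention: mean difference 7.2% (95% CI 4.0% to 10.4%; P=0.00, paired t, df=35)
```

Reading the output: the adjusted risk ratio 1.20 estimates the configured
geometric-mean effect of 1.12 (the CI reflects only 9 clusters per arm per
stratum); the control arm shows no within-arm change while the intervention
arm rose about 7 percentage points. A CONSORT-style flow diagram
(`demo/out/flow.txt`) accounts for every screened prescription by exclusion
reason, and illegible records are counted before screening.

Other subcommands: `stratcrt design` (clusters required from a YAML spec),
`stratcrt allocate`/`reveal` (sealed stratified 1:1 randomization),
`stratcrt filter` (screening + adjudication only), `stratcrt report` (full
pipeline from a run-config file).

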