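# medimr

Two-sample Mendelian randomization (MR) with mediation decomposition and
metabolite-set enrichment, for studies that link gut-microbiota taxa to a
binary disease outcome (e.g. hepatocellular carcinoma, HCC) through serum
metabolite mediators, using only GWAS summary statistics from three
independent cohorts.

## Who this is for

Genetic epidemiologists running a screening design of the form
*taxon → metabolite → disease*: hundreds of candidate exposures (microbial
taxa) and mediators (metabolite levels or ratios), each with its own
summary-statistics table, one binary outcome on the log-odds scale, and no
individual-level data. The package provides the whole chain — instrument
selection, harmonization, estimation, diagnostics, mediation, enrichment —
as a library plus a `medimr` command-line tool, and a synthetic-data
generator so every stage can be exercised and calibrated without any
download.

## The model

For each trait pair, genetic instruments are variants passing
P < 1 × 10⁻⁵ for the exposure, pruned by greedy LD clumping
(r² < 0.001 within 500 kb) and required to have F-statistic > 10, where
PVE = β²/(β² + n·se²) and F = PVE·(n − 2)/(1 − PVE). After aligning both
tables to the same effect allele, each variant j gives a Wald ratio
β̂_j = β_out,j / β_exp,j, and:

- **IVW**: β̂ = Σ w_j β̂_j / Σ w_j with w_j = β²_exp,j / se²_out,j —
  equivalently a zero-intercept weighted regression of outcome betas on
  exposure betas. Fixed-effect SE (Σ w_j)^(−1/2); under the default
  multiplicative random-effects model the SE is inflated by
  max(1, √(Q/(k−1))).
- **MR-Egger**: the same regression with a free intercept; a nonzero
  intercept indicates directional horizontal pleiotropy (t test, k−2 df).
- **Weighted median**: consistent when instruments carrying ≥ 50 % of the
  weight are valid; SE by seeded parametric bootstrap.
- **Diagnostics**: Cochran's Q (chi-square, k−1 or k−2 df), leave-one-out,
  and single-variant tables.

Mediation follows the product-of-coefficients decomposition: with
Beta_total the exposure→outcome IVW effect, Beta_1 the exposure→mediator
effect and Beta_2 the mediator→outcome effect,

    Beta_12  = Beta_1 × Beta_2          (indirect effect)
    Beta_dir = Beta_total − Beta_12     (direct effect)

computed for every exposure and mediator that survive IVW screening at
P < .05. Mediator sets are finally tested for pathway over-representation
with the hypergeometric upper tail against a GMT library, with
Benjamini–Hochberg FDR.

## Worked example

Simulate a three-cohort triplet with a planted mediated path
(β₁ = 0.3, β₂ = 0.5, direct effect 0.2, hence total effect 0.35), then run
the full pipeline:

```sh
medimr simulate --seed 7 --k 20 --out demo/bundle
# write demo/config.yaml pointing at the bundle (RunConfig.from_bundle does this)
medimr run-all --config demo/config.yaml
```

`demo/out/mediation.tsv` then contains (display columns):

```
    exposure  beta_total  beta_1  or_1  mediator      beta_2  or_2  beta_12  beta_dir
exposure_sim      0.3743  0.2491  1.28  mediator_sim  0.3749  1.45   0.0934    0.2809
```

i.e. the cascade found the planted mediator: the estimated total log-odds
effect 0.3743 (truth 0.35) splits into an indirect part 0.0934 through the
metabolite and a direct remainder 0.2809 — single-run estimates, within
sampling noise of the planted 0.15/0.20 split. `mr_exposure_outcome.tsv`
holds the three-method table with heterogeneity and pleiotropy columns:

```
       trait  nsnp          method   beta  or_  ci_low  ci_high  pvalue       q  q_pvalue  intercept  intercept_pvalue
exposure_sim    20         ivw_mre 0.3743 1.45    1.24      1.7  0.0000 18.2880    0.5033     0.0203             0.342
exposure_sim    20           egger 0.1955 1.22    0.82      1.8  0.3410 17.3355    0.5002
exposure_sim    20 weighted_median 0.3046 1.36    1.08      1.7  0.0078
```

No heterogeneity (Q p = .50) and no directional pleiotropy (intercept
p = .34), as simulated. All report files keep full-precision parallels of
every rounded column.

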