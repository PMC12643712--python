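# Methods

## Pipeline overview

The pipeline estimates causal effects of microbial-taxon exposures on a
binary disease outcome, screens serum metabolites as mediators, and
decomposes significant exposure effects into indirect (through a
mediator) and direct parts. All estimation is two-sample summary-level
MR: every trait is represented only by a per-variant table of
(effect allele, other allele, beta, SE, p, EAF, n), and the three trait
groups are assumed to come from non-overlapping cohorts.

Stages, in execution order:

1. **Instrument selection** (per exposure or mediator): keep variants
   with p < `iv.p_threshold` (default 1e-5, the conventional relaxed
   threshold for small-n microbiome and metabolite GWAS); greedy LD
   clumping at r² < `iv.clump_r2` (0.001) within `iv.clump_kb` (500 kb);
   drop instruments with F ≤ `iv.f_min` (10). With the strict p-screen
   and these formulas the F filter is usually vacuous (p < 1e-5 implies
   F ≈ z² > 19), but it binds when the reported p-value and the
   reported beta/SE disagree, which happens in real tables.
2. **Harmonization**: align outcome betas to the exposure's effect
   allele (swap → sign flip, complementary alleles → strand flip first).
   Palindromic variants are resolved by allele-frequency concordance and
   dropped when either EAF is within 0.5 ± `palindrome_window` (0.08) or
   missing.
3. **Estimation**: IVW (default multiplicative random-effects),
   MR-Egger and weighted median (k ≥ 3), with odds-ratio conversion
   OR = exp(β), Wald 95 % CI.
4. **Diagnostics**: Cochran's Q for the IVW and Egger fits, the Egger
   intercept as the pleiotropy probe, leave-one-out and single-variant
   tables.
5. **Mediation cascade**: exposures and mediators are screened on the
   outcome at raw p < `alpha_screen` (.05, no multiplicity correction —
   an optional Benjamini–Hochberg switch exists but is off by default to
   match common screening practice); for each significant pair the
   exposure→mediator leg is estimated with the exposure's instruments,
   and qualifying paths are decomposed as Beta_12 = Beta_1·Beta_2,
   Beta_dir = Beta_total − Beta_12. A proportion-mediated column
   (Beta_12/Beta_total) is reported and explicitly labeled as derived.
   No sign-consistency constraint is imposed between Beta_1 and Beta_2;
   mixed-sign paths are legitimate. No SE is attached to Beta_12 (a
   delta-method extension hook exists but is out of scope).
6. **Enrichment**: hypergeometric upper tail of the mediator set against
   each pathway of a GMT library, background = the library's full
   metabolite universe (the default behaviour of common web tools;
   configurable), BH-FDR across pathways.

## Estimator conventions

- IVW weights are β²_exp/se²_out on Wald ratios (first-order SEs; no
  exposure-side error propagation), identical to 1/se²_out weights in
  the regression form. The multiplicative random-effects SE uses the
  floor max(1, √(Q/(k−1))): it never deflates below fixed-effect. The
  floor makes the estimator slightly conservative under the null — in
  the generator's null calibration the fixed-effect IVW rejects at
  5.0 % and the random-effects variant at ≈ 3 %, so calibration checks
  target the fixed-effect form.
- IVW p-values use the normal reference; Egger uses t with k−2 df.
- Egger orients every pair to β_exp > 0 before fitting, so the sign of
  the intercept is interpretable as pleiotropy in the direction of the
  exposure-increasing allele.
- The weighted median interpolates the midpoint-adjusted cumulative
  weight function at ½; its SE is a parametric bootstrap (default
  n_boot = 1000) with a mandatory seed — there is no silent
  nondeterminism anywhere in the pipeline, and re-running a
  configuration reproduces every report byte for byte.
- Q p-values of exactly 1 (perfectly homogeneous sets) are reported as
  1, not clamped; input p-values of exactly 0 are clamped to the
  smallest positive float with a logged warning because downstream
  ranking needs a finite order.
- Degenerate inputs: β_exp = 0 raises a degenerate-instrument error;
  k below an estimator's minimum raises with the minimum named;
  multiplicative random effects at k = 1 falls back to fixed with a
  logged note.

## Display rounding

Report TSVs round OR/CI to 2 decimals and betas/p to 4 (the printed
precision of the tables this layout mirrors); every rounded column has a
`*_full` companion at full precision, so fixtures can match printed
values without losing machine accuracy.

## The synthetic-data generator

`simulate_triplet` emulates the three cohort tables with known causal
structure. Per instrument j: γ_j ~ N(0, gamma_sd²) resampled until its
exposure p-value clears 1e-5 (so selected instruments exist by
construction); mediator effect α_j = β₁γ_j; outcome effect
Γ_j = β_dir·γ_j + β₂α_j + π_j with π_j ~ N(pleiotropy_mean,
pleiotropy_sd²). SEs use the closed form (2·n·EAF(1−EAF))^(−1/2); the
binary outcome uses effective size v·n_out with
v = case_fraction(1 − case_fraction), preserving the scale of a
rare-disease GWAS (default case fraction 0.0094, i.e. 1866 cases in
197,611) without individual-level simulation. The mediator additionally
carries `k_med_instruments` (10) loci of its own with effects
δ ~ N(0, delta_sd²) resampled at n_med — the mediator→outcome leg is
instrumented by these, as a metabolite GWAS would be.

Default scales: n_exp = 18,340, n_med = 8299, n_out = 197,611
(the cohort sizes of the emulated design), k = 10 instruments (near the
per-taxon median of such screens), β₁ = 0.3, β₂ = 0.5, β_dir = 0.2
(total 0.35). `gamma_sd` defaults to 0.08 so that taxon-SNP effects on
the mediator (β₁·γ ≈ 0.03) stay below the 1e-5 threshold at n_med: the
taxon and metabolite instrument sets remain disjoint, as in the emulated
design. With larger γ scales the taxon loci become genome-wide
significant metabolite loci and enter the mediator's instrument set,
where the direct path acts as correlated pleiotropy and biases β₂
upward — a real phenomenon of overlapping instruments, but not the
regime the screening design assumes. Strong-instrument calibration runs
(gamma_sd = 0.25) therefore disable either the mediation path or the
mediator-own loci.

Effect alleles are coded as exposure-increasing (γ ≥ 0, switchable via
`orient_positive`), the orientation under which a positive
`pleiotropy_mean` is directional for the Egger intercept. Instrument
resampling (rather than truncation-corrected draws) is used to hit the
p-threshold; the winner's-curse bias this induces is negligible at the
default scales because exposure leads are written without additional
sampling noise (the accepted draw *is* the observed estimate), so Wald
ratios remain unbiased. A fifth of outcome rows are stored with swapped
allele coding (negated beta, mirrored EAF) so harmonization is exercised
end to end.

What the generator does **not** emulate: realistic allele-frequency
spectra, population stratification, sample overlap between cohorts,
binary-trait non-collapsibility, reverse causation, or correlated
pleiotropy beyond the constant/Gaussian direct effects above. Passing
calibration tests therefore demonstrates internal consistency of the
estimators under the stated generative model, not robustness to those
real-data pathologies.

## Calibration results computed by the suite

The acceptance suite and `scripts/acceptance.py` recompute, at fixed
seeds: mean recovered total effect over 200 replicates (k = 30,
gamma_sd = 0.25); mean recovered indirect effect through the full
cascade over 200 replicates at default scales; the fixed-effect IVW
rejection rate at the null over 500 replicates (expected within
5 % ± 2 %); and the Egger-intercept detection rate under constant
pleiotropy 0.05 (k = 30). Stochastic tolerances are ±2 Monte-Carlo SEs
computed from the replicate set itself. These replicate counts keep the
whole suite under a minute on one CPU while leaving Monte-Carlo error
well below the tolerances.

## Numerical and design choices

- LD is consumed as a sparse pair list; an absent pair means r² = 0.
  Cross-chromosome pairs are never clumped regardless of r² entries.
- Clumping ranks by (p, variant_id): the lexicographic tiebreak makes
  runs reproducible and the output independent of input row order.
- PVE uses the standardized-trait form β²/(β² + n·se²) by default
  because it needs no allele frequency; the EAF form 2β²·EAF(1−EAF) and
  the Wald F form (β/se)² are config switches.
- Coordinates are 1-based and used only for clumping windows; genome
  build consistency across tables is the caller's responsibility.
- Harmonization extends the action vocabulary with
  `dropped_incompatible` for shared ids whose allele pairs cannot be
  reconciled by swap or strand flip, keeping the conservation identity
  (kept + dropped = intersection) exact.
- Strict mode aborts on any invalid row; the default permissive mode
  drops the row with a logged, machine-parsable reason
  (`DROP variant=... reason=...`), matching typical summary-statistics
  hygiene.

## Known limitations

Multivariable MR, Steiger directionality filtering, MR-PRESSO outlier
correction, mode-based estimators, proxy-SNP lookup, liftover and
multi-allelic handling are deliberately not implemented. Enrichment
p-values depend strongly on the chosen background; with the default
library-universe background they are not comparable across libraries.
The mediation decomposition is a linear product-of-coefficients
approximation applied on the log-odds scale; with a rare outcome the
non-collapsibility error is small but not zero.
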