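# Methods

## The models

### Random-intercept panel model (RI-PM)

For a trait measured at occasions t = 1..T (three school ages for the
academic traits, four for cigarettes/day), the observed composite is

    y_t = μ_t + η + r_t
    r_1 = e_1,   r_t = ρ_{t−1} r_{t−1} + e_t,   e_t ~ N(0, θ_t)

with all loadings fixed to 1, free occasion intercepts μ_t, a random
intercept η with mean 0 and variance ψ (the *stable trait*), and
occasion-specific residual factors r_t linked by autoregressive paths.
The implied covariance follows the recursion Var(r_t) = ρ²_{t−1}
Var(r_{t−1}) + θ_t, Cov(r_s, r_t) = (∏_{u=s..t−1} ρ_u) Var(r_s). Omitting
the AR paths when ρ ≠ 0 pushes occasion covariance into ψ and biases the
stable-trait variance upward; a directional test covers this.

Conditional models regress η on predictors x (one or both PGSs plus sex
and five ancestry PCs): η = Γ'x + ζ, ζ ~ N(0, ψ). Predictors are treated
as fixed regressors; standardized coefficients are Γ_j·sd(x_j)/sd(η) with
sd(η)² = Γ'Σ_x Γ + ψ taken from the sample predictor moments.

**Estimation.** Casewise FIML: persons are grouped by missing-data
pattern and each pattern contributes its observed-margin Gaussian
likelihood. Likelihood evaluations use per-pattern sufficient statistics
(Y'Y, Y'X, X'X and sums), so an evaluation costs O(T³) per pattern
independent of n. ψ and θ_t are optimized on the log scale, which keeps
the implied covariance positive definite throughout the search; ρ_t are
unbounded. Optimization is quasi-Newton (BFGS) on the per-case mean
deviance from method-of-moments starts (ψ₀ = mean off-diagonal
covariance, θ₀ = diagonal minus ψ₀, ρ₀ = 0), converged at gradient norm
1e−6. The parameter covariance is the inverse numerical Hessian.
Family clustering is deliberately ignored in point estimation (each twin
contributes a likelihood term); inference comes from the family-clustered
bootstrap instead.

### MAP factor scores

Under the fitted normal model the posterior of η given a person's
observed occasions is normal, so the posterior mode equals the posterior
mean:

    score = Γ'x + ψ·1' Σ_obs⁻¹ (y_obs − μ_obs − 1Γ'x)

Reliability for an observation pattern is Var(score)/ψ = ψ·1'Σ_obs⁻¹1,
which lies in [0, 1] and is non-decreasing as occasions are added.
Mediation uses scores from the *unconditional* fits, so PGS effects are
estimated downstream rather than injected through the scoring step; the
cost is the usual two-step attenuation of path coefficients by score
unreliability (not corrected here, as in the design being emulated).

### Mediation path model

Exogenous block (two PGSs, sex, five PCs) → five RI scores → age-residual
attainment, every equation by least squares. For this fully recursive,
just-identified system the equation-wise fit coincides with ML path
analysis, and total = direct + Σ indirect holds at machine precision on a
common complete-case base (cases missing any model variable are dropped;
with MCAR attrition this is unbiased). Mediator residual covariances are
the covariances of the equation residuals (identical regressor sets, so
this is the seemingly-unrelated ML solution). Proportion mediated is
suppressed when |total| ≤ .01.

**Inference.** Clustered nonparametric percentile bootstrap: families are
resampled with replacement to the original family count (both twins move
together, multiplicity preserved), all statistics recomputed per draw,
95% CIs as the 2.5/97.5 empirical percentiles (1000 draws by default).
Failed refits are dropped and counted; more than 5% failures aborts. The
auxiliary p-value required by the significance rule (CI excludes 0 AND
p < .005) is a two-sided normal approximation from the bootstrap SE — the
design leaves the p-value source open, and the percentile CI remains the
primary criterion.

## The synthetic cohort

The generator emulates a two-cohort longitudinal twin-family study:
1,881 same-sex twin pairs (64% MZ), two thirds recruited at age 11
("younger cohort", assessed at 11/14/17) and one third at 17 ("older
cohort", first assessed at 17); cigarettes/day is assessed at 14/17/21/24
and attainment once in adulthood (age ~29.4 ± 3.9).

**Polygenic scores.** Bivariate standard normal with cross-correlation
−.23; MZ co-twins share identical scores, DZ co-twins correlate .50 (the
expected sibling sharing). PCs are pure noise covariates and sex has zero
default effect — they exercise the covariate plumbing, since the real
confounding structure is not reconstructible from printed results.

**Random intercepts.** Standardized trait RIs are η = B·PGS + ε with B
the published 2-PGS standardized path estimates — these reproduce the
published marginal PGS–RI correlations exactly (e.g. −.09 + .22·(−.23) =
−.14) — and ε an ACE-style residual (additive-genetic share .40 shared
fully by MZ and half by DZ twins, common environment .30, unique .30;
the published meta-analytic fractions for attainment). The residual
cross-trait covariance is the published RI correlation matrix minus the
PGS-explained part (verified positive definite). No biometric model is
fit downstream; this exists to make family clustering realistic for the
clustered bootstrap.

**Occasion panels.** Per trait, (ψ, θ_t, ρ_t) are solved exactly from the
published per-age SDs and the three occasion correlations — the
3-occasion model is just-identified, with ψ = (c13·V2 − c12·c23)/(c13 +
V2 − c12 − c23). Composites are generated on a continuous scale; the
bounded-grade ceiling of real instruments is not emulated (≈8% of GPA
values exceed 4), a deliberate trade that keeps means, SDs and
correlations exactly calibrated.

**Informants.** Two-informant traits split the latent composite as
c ± δ with Var(δ) = V(1−r)/(1+r), hitting the published informant
correlations (GPA .79, motivation .51, discipline .62) while keeping the
informant mean exactly the calibrated composite. Teacher ratings (1–3
teachers, 75% with ≥2) are mean-centered within person. The published
.55 correlation between self/parent and teacher motivation is cross-trait
and is matched by correlating the occasion-residual innovations of the
two motivation traits; the innovation correlation has a closed form
because the implied occasion correlation is linear in it.

**Cigarettes.** A latent standard-normal panel (stable share .35 of
occasion variance — inside the .20–.47 range implied by the academic
traits, since the stable share is not identified from printed values) is
thresholded into 0–6 categories using maximum-entropy pmfs matching the
published per-occasion means and SDs; the latent adjacent correlations
are solved with an exact Hermite-series map so the *coded* variable shows
the published .67 lag-1 autocorrelation where attainable (the age-14
occasion is too zero-inflated; its latent correlation caps at .97 and the
coded 14→17 autocorrelation comes out ≈.57). Each category is emitted as
a representative raw cigarettes/day value, so the measurement step's
binning recovers the category exactly.

**Attainment.** A latent liability combines a standardized age-at-report
score, the PGSs and the five RIs with the published standardized paths,
plus noise to unit variance, thresholded at the category proportions.
The printed category percentages sum to 94.7%; the default assigns the
unaccounted 5.3 points to the heterogeneous middle category
(vocational/some college/associate's), preserving the other five printed
shares. Because thresholding attenuates linear association, the age and
structural weights are inflated by the closed-form categorization
attenuation factor (Cov(cat, z) = Σ_k v_k(φ(t_{k−1}) − φ(t_k))), so the
*categorical* variable carries the target effects — r(age, EA) = .27 by
construction. Residual EA–RI correlations on the categorical scale still
come out slightly below the printed factor-score values (≈.50 vs .52 for
GPA); two-step shrinkage in the pipeline attenuates them further, most
visibly for cigarettes.

**Missingness.** MCAR by default: pair-level visit attrition with
retention .914 (age 14, younger cohort), .863 (17, younger), .717 (21),
.866 (24); the older cohort is missing ages 11/14 by design;
person-occasion teacher availability .699/.720/.598; attainment missing
for 7.9%. Unobserved rows carry no value. What passing tests show is
therefore recovery under MCAR; the generator does not emulate informative
dropout (a hook for discipline-dependent dropout would be the natural
stress-test extension), ordinal measurement of the academic composites,
or genotype-level structure (no LD, no population stratification beyond
noise PCs).

## Numerical choices and problem sizes

- Default bins for cigarettes/day → 0–6: 0 / <1 / 1–5 / 6–10 / 11–15 /
  16–19 / ≥20 (only the endpoints are fixed by the instrument
  description; interior bounds are config-overridable).
- One-factor CFA: ML over missing-data patterns, factor variance fixed to
  1, uniquenesses on the log scale; Heywood cases flagged at uniqueness
  < 1e−4 of the item variance; fits with mean communality < .05 flagged
  degenerate. Scores by the regression method on observed items.
- Rounding in rendered tables: two decimals, half away from zero, after
  snapping binary floats to 10 decimal digits.
- Statistical test/acceptance problem sizes were chosen to keep the whole
  suite at desk scale while leaving Monte-Carlo error well inside the
  asserted tolerances: calibration checks use 8,000–25,000 families,
  parameter recovery 100 replications × 2,000 families, bootstrap
  coverage 200 replications × 500 families × 200 draws, LR-null
  calibration 120 replications.
- All randomness flows from `numpy.random.default_rng` seeded from the
  cohort seed (simulation and missingness use distinct child streams, so
  the same cohort can be re-missing-ed deterministically).

## Known limitations

- Point estimation ignores family clustering; only bootstrap inference
  accounts for it (matching the emulated design).
- Factor-score mediation is two-step: path coefficients are attenuated
  relative to a joint latent-variable fit, and no reliability correction
  is applied.
- The cigarettes model treats the 0–6 code as continuous in the RI-PM
  (as in the emulated analysis); its latent calibration is exact for
  marginals and lag-1 correlations, not for higher-order joint moments.
- Standard errors reported outside the bootstrap (inverse-Hessian) ignore
  clustering and the standardization's sampling variability.
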