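# Methods

## The design

The target parameter is the causal effect of a parent's BMI on their hazard
of a first long-term (≥31-day) sick-leave spell. Offspring BMI serves as an
instrument: it is associated with parental BMI through shared genetic and
environmental factors, while the parent's own health cannot plausibly act
on it. Under the usual instrumental-variable conditions — relevance, no
uncontrolled common cause of instrument and outcome, and no effect of the
instrument on the outcome except through the exposure — the Wald ratio of
the instrument–outcome and instrument–exposure associations identifies the
exposure effect. The design's main value is robustness to reverse
causation: illness-driven weight loss distorts the conventional
exposure–outcome association but leaves the offspring-based associations
intact. It does *not* remove confounding by factors transmitted across
generations (socioeconomic position, health behaviours); the bias component
table exists to display exactly that residual vulnerability.

## Estimation

**Exposure scale.** Adult BMI is standardized to z-scores within strata of
age category (<30, 30–39.9, 40–49.9, ≥50 years; half-open intervals, so an
exact 30/40/50 falls in the higher band), sex, and survey wave, using
stratum sample means and SDs (denominator n−1). Offspring under 18 are
scored against an LMS growth reference, z = ((BMI/M)^L − 1)/(LS), with the
log-limit branch ln(BMI/M)/S taken for |L| < 1e-12; L, M, S are linearly
interpolated in age between tabulated rows (grid spacing in published
references is fine enough that the interpolation method is immaterial).
Offspring aged exactly 18 use the adult strata.

**Hazard models.** Cox partial likelihood on the age axis with delayed
entry at the baseline age; competing events (disability benefit, death,
the administrative age-65 bound, end of registry follow-up) censor. Ties
are handled with the Efron approximation (ages recorded on a calendar grid
produce ties); Breslow is available and agrees to 1e-8 when event ages are
distinct. Estimation is a vectorized Newton iteration: risk-set sums at the
distinct event times are suffix cumulative sums over exit- and
entry-sorted copies of the data, using the identity
{entry < t ≤ exit} = {exit ≥ t} minus {entry ≥ t}. Covariates are centered
(the partial likelihood is exactly invariant); step-halving triggers on a
*relative* likelihood decrease of 1e-8·(1+|ℓ|), because suffix-sum
round-off jitters ℓ at that level near the optimum; convergence is declared
when the largest Newton step falls below 1e-9. Categories that contain no
events are dropped from categorical fits with a warning — their
partial-likelihood maximum is at −∞ and reporting a number would be
misleading. Confidence intervals are Wald intervals from the inverse
observed information, matching the estimate-(95% CI) presentation of the
surrounding literature.

**Adjustment.** The minimal model is baseline age as a restricted cubic
spline with five knots, interacted with survey wave. Knots sit at the 5th,
27.5th, 50th, 72.5th and 95th percentiles of baseline age (the standard
five-knot placement). The spline is the natural truncated-power basis
(K−1 = 4 columns; linear beyond the boundary knots; cubic terms scaled by
the squared boundary span for conditioning). The interaction is coded as a
wave main effect plus a separate spline block per wave — equivalent to
fitting an unrestricted smooth age curve within each wave, which subsumes
the spline main effect; this choice is recorded in report metadata. The
full model appends reference-coded dummies for education (6 levels),
occupation class (8 EGP levels, V and VI kept separate, VIII =
military/unknown), smoking (4), alcohol (6) and physical activity (4):
23 columns. Missing covariate data are handled by complete-case exclusion
only; no imputation.

**The ratio.** β̂_IV = β̂_ZY/β̂_ZX with the first-order delta-method SE
treating numerator and denominator as independent. They are computed from
the same sample, so a covariance term exists in principle; the parametric
bootstrap oracle in the test suite quantifies the quality of the
independence approximation in the strong-instrument regime (agreement
within 5% at |β̂_ZX|/se > 10). SEs recovered from printed CIs use
se = (ln u − ln l)/3.92 on the log scale for ratio estimates and
(u − l)/3.92 for mean differences. The ratio refuses to evaluate when
|β̂_ZX| ≤ se(β̂_ZX) and warns (but proceeds) when |β̂_ZX|/se < 10,
roughly F < 100 — far below the F ≈ 600–900 regime the design is intended
for, but enough to flag analyses where weak-instrument bias matters.

**Instrument strength.** Partial R² = (RSS_reduced − RSS_full)/RSS_reduced
(reported in percent) and the one-degree partial F with RSS_full/(n −
p_full) in the denominator, p_full counting the intercept. For a single
instrument, F = (r²/(1−r²))·(n − p_full) exactly, and with an
intercept-only reduced model F equals the squared t-statistic of the
instrument coefficient. Published *adjusted*-model F values generally
cannot be recovered exactly from a rounded adjusted R² and n because the
degrees-of-freedom convention for the adjustment block is not identifiable
from the printed numbers; the package therefore computes F only from data,
and the printed-value identity is exercised for minimal-adjustment models
only.

**Bias components.** For each covariate (dichotomized at conventional
cut-points: education below university level, i.e. levels 1–4 of 6; EGP
class III or below in status; daily-or-occasional smoking; alcohol ≥2–3
times/week; physical activity below 3 h light with no hard activity; plus
participation age kept continuous), two unadjusted associations are
computed: on the parent z-score (conventional) and on the offspring z-score
divided by the unadjusted instrument–exposure slope (IV). Binary covariates
use logistic regression (log-odds per SD — the scaling step makes the
log-odds vs odds-ratio choice immaterial for the conclusion), continuous
ones OLS. Each pair is rescaled by the larger absolute member, so one
member is ±1; CIs scale by the same factor, the factor is retained so the
raw estimates are exactly recoverable, and an all-zero pair is flagged
degenerate rather than scaled. Components are comparable only within a
pair, never across covariates or strata, and the exports preserve that
grouping.

**Proportional-hazards check.** Follow-up is split at the median time to
event among events; every record is episode-split there (an event exactly
at the split belongs to the early period — closed on the right), one model
with an exposure-by-period interaction is fitted, and the Wald z of the
interaction tests equality of the period HRs. Under proportional hazards
the test holds its nominal size (checked by simulation); a sign-reversing
effect is detected with high power.

## The synthetic cohort

Per family the generator draws a familial factor G ~ N(0,1), a confounder
U ~ N(0,1), and a latent illness D ~ Bernoulli(p). Parent and offspring
BMI z-scores are

    X_p = a·G + b_p·U + δ_BMI·D + ε_p ,   X_o = a·G + b_o·U + ε_o ,

with residual variances solved so Var(X_p) = Var(X_o) = 1 (configurations
that make this impossible are rejected). Sick-leave onset is exponential
given covariates — hazard r·exp(β·X_p + γ·U + δ_haz·D) from the baseline
age onward — so proportional hazards holds by construction and recovery
tests are not confounded by model misspecification. Censoring is
administrative (entry + follow-up window, capped at age 65). Closed form
used throughout the tests: cov(X_p, X_o) = a² + b_p·b_o, which equals the
regression slope and the correlation on this scale. D affects only the
parent: reverse causation concerns the parent's own outcome, and the
instrument must stay insulated from it. With b_o = 0 the instrument is
valid; setting b_o ≠ 0 deliberately breaks it for diagnostics tests.

Defaults encode the study conditions the package targets: a = √0.24
(instrument slope 0.24 SD/SD, partial R² ≈ 5.8%), b_p = 0.3, b_o = 0,
β = 0.15, γ = 0.3, p = 0.08, δ_BMI = −0.4, δ_haz = 0.5, baseline rate
0.08/person-year, entry ages uniform on (25, 60), nine years of
administrative follow-up. These give an all-cause incidence of ≈85 events
per 1000 person-years, a mean follow-up of ≈6.1 years and an event
fraction of ≈52%, matching the published cohort's order of magnitude
(incidence 78–115/1000 PY, mean follow-up 5.8–6.9 y). BMI in kg/m² is
produced by destandardizing z against built-in stratum references (women
26.6 ± 4.7, men 27.7 ± 3.6, offspring ≈24.7 ± 4.6 kg/m², with additive age
and wave shifts), or through the inverse LMS transform of a bundled
*synthetic* adolescent reference for offspring under 18 — that table has
the qualitative shape of published growth references but is not one, and
must never be used to score real data. Categorical covariates are drawn
from ordered-logistic latents loading on U, X_p and G; the default signs
reproduce the familiar pattern (low education, lower-status occupation and
inactivity with higher BMI; frequent alcohol with lower BMI; smoking with
lower own but higher offspring BMI, via a loading on G). The covariate
correlation structure is plausible rather than calibrated — no published
joint distribution exists to calibrate against.

What the generator does **not** emulate: calendar-time entry (waves map to
a simple additive BMI shift, not distinct recruitment periods), benefit
grading and repeated spells (only the first spell matters here), death and
emigration as explicit competing processes, assortative mating, and any
direct offspring-to-parent pathway. Passing tests therefore demonstrate
the estimator's internal validity under the stated structural model, not
the truth of the IV assumptions in any real cohort.

## Validation design and known limitations

The test suite validates each stage against an independent route: the Cox
solver against a brute-force partial-likelihood grid oracle and against
lifelines (Efron ties, delayed entry); the spline basis against scipy
natural cubic interpolants; the delta-method SE against a parametric
bootstrap; partial F against the squared-t identity; and the ratio
arithmetic against published worked examples. Monte-Carlo studies check
parameter recovery (200 replicates of n = 20,000), CI calibration
(500 replicates; empirical coverage ≈94%), and the qualitative
reverse-causation signature: with a pronounced illness mechanism
(p = 0.10, δ_BMI = −1.5, δ_haz = 1.5) the conventional categorical curve
is J-shaped while the offspring-based curve shows no low-end elevation.
Monte-Carlo problem sizes (replicate counts and n per replicate) were
chosen to keep the whole suite around a minute on one CPU while leaving
the Monte-Carlo error well below the effects being tested.

One bias is documented rather than engineered away: **hazard-ratio
non-collapsibility**. The reduced-form Cox coefficient is a marginal log
HR, attenuated relative to the conditional one by the unmodelled hazard
heterogeneity (γ·U, the illness term, and the residual of X_p given X_o),
increasingly so as cumulative risk accumulates. The OLS denominator has no
analogous attenuation, so the ratio inherits the numerator's shortfall.
Under the default study conditions (event fraction ≈52%) the asymptotic
IV estimate is ≈0.144 per SD against a generating β = 0.15 — a relative
attenuation of ≈4%, far inside the statistical uncertainty of any single
analysis of this size (per-dataset se_IV ≈ 0.04 at n = 20,000) but visible
to a 200-replicate mean, where the recovery test resolves it and fails its
±2-MC-SE band. This is a property of Wald ratios built on hazard ratios,
not of the implementation; analyses at lower event fractions attenuate
proportionally less. Other limitations: numerator and denominator are
treated as independent in the variance (see above); families contributing
two parents are analysed in both sex strata without a clustering
correction, so sex-specific results are not independent; and no
competing-risks (Fine–Gray) or multi-instrument machinery is provided —
the single-instrument ratio is the method, by design.
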