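# Methods

## Model

For subject i with covariate vector x_i, the flexible parametric survival
model places a restricted cubic spline in log time on a transformed survival
function:

g(S(t | x_i)) = η₀ + η₁ ln t + Σ_j η_{j+1} v_j(ln t) + β′x_i = η_i(t)

with three choices of link g:

| scale  | g(S)                  | S(η)            | 0-knot family |
|--------|-----------------------|-----------------|---------------|
| hazard | ln(−ln S) = ln H      | exp(−e^η)       | Weibull       |
| odds   | ln((1−S)/S)           | 1/(1+e^η)       | log-logistic  |
| normal | −Φ⁻¹(S)               | Φ(−η)           | lognormal     |

The derived variables are the standard natural-spline construction: for
internal knot k_j with boundaries k_min < k_j < k_max,

v_j(x) = (x−k_j)₊³ − λ_j (x−k_min)₊³ − (1−λ_j)(x−k_max)₊³,
λ_j = (k_max−k_j)/(k_max−k_min),

which is C² everywhere and exactly linear outside [k_min, k_max]; the linear
tails are what make extrapolation of the cumulative hazard beyond the
observed follow-up well defined. Boundary knots sit at the extremes of the
*uncensored* log event times; internal knots at equally spaced centiles of
the same (one knot → the median). "Zero knots"/"one knot" always count
internal knots — the reduction of each scale to its parametric family only
holds for the boundary-only (linear) spline.

The censored log-likelihood is

ℓ = Σ_censored ln S(t_i) + Σ_events [ ln(−dS/dη)(η_i) + ln(dη_i/d ln t) − ln t_i ],

so the event term needs the spline's analytic derivative in log time. The
model is proper only where dη/d ln t > 0 at event times; when an optimizer
iterate violates this, the offending contributions are replaced by a steep
linear penalty (slope 10⁴ per unit of negative derivative, with the log term
floored at ln 10⁻¹²), which pushes iterates back into the proper region while
keeping the objective finite and (piecewise) differentiable. A solution that
still sits in the penalized region is reported with `converged=False`. All
exponentials are clamped at |η| ≤ 700 and the odds/normal links use
log-sum-exp / `log_ndtr` forms, so likelihoods stay finite over the entire
float range.

## Fitting

Maximum likelihood by BFGS with analytic gradients (gradient tolerance 1e-8,
up to 3 restarts from perturbed starts before flagging non-convergence).
Starting values come from moment matching of ln T on the no-knot family of
the chosen scale — Gumbel moments for hazard (η₁ = (π/√6)/sd, η₀ = −mean·η₁ −
0.5772), logistic moments for odds, normal moments for lognormal — with
internal-knot and regression coefficients started at zero. On censored Weibull
data at n=2000 the fitted no-knot log-likelihood agrees with a direct (λ, γ)
parameterization MLE to better than 1e-6.

Standard errors come from the inverse of a finite-difference Hessian of the
analytic gradient (delta method); they are reported for completeness but
nothing downstream depends on them.

AIC = −2ℓ + 2k and BIC = −2ℓ + k ln n count k = 1 + n_basis + |β|: intercept,
spline terms and the survival-stage regression coefficients. The PLS
extraction stage is *not* counted — models are compared as if the components
were fixed predictors, which matches how such comparisons are usually
tabulated but understates the effective dimension of both composites equally.

## PLS stage

Univariate-response NIPALS with X-deflation: covariates are standardized to
training mean 0 / variance 1 (ddof=1), the working response is the
standardized log observed follow-up time, and each weight vector w_c ∝ X_c′y
is normalized and sign-fixed (largest-magnitude entry positive) for
platform-independent reproducibility. Censoring is ignored at the extraction
stage — the response is the observed time whether or not it was an event —
and handled entirely by the survival stage. A censoring-aware extraction
(e.g. deflating on Cox residuals) is a known alternative and deliberately out
of scope.

Scores satisfy T = X_std·R with R = W(P′W)⁻¹; held-out subjects are scored
with the stored training center/scale and R. Component coefficients b_comp
from the survival stage are reported per covariate as b_cov = R·b_comp (on
the standardized covariate scale), so T·b_comp = X_std·b_cov exactly.
C defaults to 2 — the smallest count that exercises multi-component code
paths — and is user-settable; no automatic component selection is attempted.
Direct unregularized fits with p ≥ n are refused with an explicit error.

## Cox benchmark

The survival stage of PLS-Cox maximizes the Efron-tie-corrected partial
likelihood (via lifelines, with the Newton tolerance tightened to 1e-10 so
coefficients reproduce direct partial-likelihood solves to ~1e-8). The
baseline cumulative hazard is the Breslow estimator at reference (zero)
covariate values. Zero-variance covariates are held at coefficient zero
rather than rejected. Note that replicating every subject does *not* leave
the Efron estimate exactly invariant (duplication creates ties, and the Efron
correction averages within them); invariance to monotone time transformations
holds exactly and is what the tests assert.

AIC/BIC for the Cox row use the partial likelihood in place of a full
likelihood. Comparing that against full-likelihood criteria from the
parametric fits is methodologically debatable — the partial likelihood omits
the baseline-hazard information and is systematically lower — so the Cox row's
criteria should be read as the conventional benchmark tabulation, not as a
calibrated likelihood comparison. The comparison harness additionally reports
out-of-sample log-likelihood on the held-out partition, which is the fairer
cross-family number.

## Simulator

Covariates: p columns split into min(10, p) near-equal blocks; block b is
multivariate normal with AR(1) correlation ρ_b^|i−j|, ρ_b equally spaced over
[0, corr_max]. With the defaults (p=200, corr_max=0.9) realized pairwise
correlations span ~0 to ~0.9 and the target matrix is positive definite by
construction. Event times follow a Weibull proportional-hazards model,
H(t|x) = λ t^γ e^{x′β}, drawn by inverse transform
T = (−ln U/(λ e^{x′β}))^{1/γ}, with administrative (Type I) censoring at the
horizon. Defaults: n=100, p=200, λ=0.1, γ=1.5, horizon=5 — under which about
two thirds of subjects experience the event (S(5) = e^{−0.1·5^1.5} ≈ 0.327
censored at β=0). True effects default to a sparse vector (first 10
covariates at 0.2, rest zero) and are configurable; parameter-recovery
checks use β=0 so the marginal is exactly Weibull. All randomness flows
through `numpy` Generators seeded from the spec seed (separate streams for
covariates and times), so datasets are bit-reproducible.

The 70:30 split is read as 70% training / 30% test (ceil(n·0.7) training
rows), drawn as a uniform random partition from its own seed.

What the simulator does *not* emulate: covariate measurement scales other
than Gaussian (real surveillance covariates are largely categorical),
informative or covariate-dependent censoring, non-proportional hazards, and
non-monotone baseline hazards. Passing tests therefore demonstrate correct
recovery under a correctly specified proportional-hazards Weibull truth with
Gaussian collinearity — not robustness to the messiness of real survey data.

## Numerical and design choices

- Knot placement uses uncensored subjects only; ties that would collapse two
  centile knots raise an error rather than silently merging.
- The comparison harness fits all seven models on one shared split and one
  shared decomposition per C; non-converged fits stay in the table, flagged,
  and are excluded from the AIC ranking.
- Problem sizes in the test and acceptance protocols (n=5000 × 20 seeds for
  parameter recovery; n=400 datasets for the family-reduction checks; 20
  seeds of the default n=100, p=200 generator for the model-comparison
  direction) were chosen to keep Monte-Carlo error well inside the asserted
  tolerances while remaining quick on a single CPU.
- The directional model-comparison claim (spline composites beating PLS-Cox
  on AIC in most seeds) is partly driven by the partial-vs-full likelihood
  mismatch described above; it is reproduced as the standard tabulation and
  documented rather than endorsed.

## Limitations

Time-varying effects, interval censoring, left truncation, stratification,
frailty, penalized splines and automatic knot/component selection are out of
scope. Uncertainty for the back-projected covariate coefficients is not
propagated through the PLS stage (components are treated as fixed
predictors).
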