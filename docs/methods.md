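# Methods

## Data model

A patient is a cumulative rectal DVH plus three binary clinical flags:
antihypertensive/anticoagulant use (AH/AC), grade 1–2 acute GI toxicity,
and the outcome, grade 1–2 late GI toxicity (toxicity after three months
from treatment completion). Doses are physical doses in Gy with no
EQD2/linear-quadratic conversion: the emulated treatment delivers 2 Gy
per fraction throughout (76 Gy in 38 fractions), so fractionation
corrections would be a constant. Cumulative curves must start at volume
fraction 1, be non-increasing, and live on a strictly increasing dose
grid; numeric noise within 1e-6 is clamped, anything larger is rejected
naming the offending patient. Absolute-volume DVH exports are
normalized per patient by that patient's maximum tabulated volume, since
exports do not always start at the full organ volume.

Cumulative-to-differential conversion assigns each interval's volume
`V(dᵢ) − V(dᵢ₊₁)` to the interval midpoint; the last bin keeps its own
dose. The midpoint convention is unbiased for slowly varying curves and
makes the re-accumulation round trip exact at the original bin edges.

## LKB fitting

The likelihood is the Bernoulli log-likelihood of the outcomes with
per-patient probabilities `Φ((gEUD − D₅₀)/(m·D₅₀))`. Numerical choices:

- **gEUD in log space.** `gEUD = exp(n · logsumexp(log vᵢ + log dᵢ / n))`.
  For serial organs `1/n` reaches several hundred during optimization and
  the naive power sum overflows; the log-space form is exact to machine
  precision (the test suite checks agreement with the naive formula at
  `n ≥ 0.05` to 1e-10 relative).
- **Probability clipping** to `[1e-12, 1 − 1e-12]` before the log, so a
  degenerate parameter set yields a very bad but finite likelihood
  instead of `−inf`, which Nelder–Mead handles poorly.
- **Unconstrained reparameterization** `(log D₅₀, log m, logit n)`
  instead of penalties, keeping the simplex unconstrained while
  enforcing `D₅₀, m > 0` and `n ∈ (0, 1]`.
- **Multistart**: the default grid is D₅₀ ∈ {60, 80, 100} Gy × m ∈
  {0.2, 0.4} × n ∈ {0.05, 0.2, 0.5} (18 starts); the reported optimum is
  the best over starts. Convergence tolerances: 1e-8 on the
  log-likelihood, 1e-6 on parameters, at most 5000 iterations per start.
- A cohort with a single outcome class raises a non-identifiability
  error rather than returning a boundary fit.

## Profile likelihood, contours, bundle

Per-parameter 95% intervals scan the named parameter away from its ML
estimate **with the other two fixed at their ML values** (an optional
full-profile mode re-optimizing nuisances exists but is not the
default). The threshold is `LLH_max − χ²(0.95, df)/2` with df = 1 by
default (configurable); the crossing is bracketed on a 2% geometric grid
and refined by Brent root-finding. If the threshold is not crossed
inside the admissible range (D₅₀ ∈ [1, 10⁴] Gy, m ∈ [1e-4, 10],
n ∈ [1e-6, 1]) the endpoint is reported at the range bound with an open
flag rather than fabricating a crossing.

Iso-likelihood contours in the three parameter planes evaluate the
surface on a geometric grid (default 60×60 spanning 2.5-fold around the
optimum), trace the level set by marching squares, and then project each
traced point onto the exact level set by root-finding along the ray from
the ML estimate in log-parameter space. The refinement removes the
linear-interpolation error of the coarse grid: traced points satisfy
`|LLH − threshold| < 1e-9` instead of O(0.1–1). Contours clipped by the
grid boundary are flagged open. Using df = 1 for both the 1-D intervals
and the 2-D contours makes the contour's extreme coordinate along each
axis coincide with the corresponding profile endpoint, which the suite
checks.

The NTCP confidence bundle evaluates one probit curve per contour
parameter set over a dose grid and reports the pointwise min/max
envelope; the best-fit curve is included, so it lies inside the envelope
by construction.

## Bootstrap

Each run draws `subsample_size` patients (default: the cohort size; the
"number of folds of 80" convention of the emulated study corresponds to
`subsample_size=80` at n = 84) **with replacement** — a
without-replacement subsampling mode exists behind a flag — from a
seeded `numpy` generator, refits by ML, and records the parameters.
Resamples with a single outcome class or failed fits are skipped and
counted; if fewer than 10% of runs survive the whole procedure errors
with diagnostics. The default refit uses a single Nelder–Mead start at
the full-cohort optimum: resamples are perturbations of the full cohort,
so the full-cohort optimum is an excellent start, and this keeps
2000-run analyses at desk scale; a multistart refit is available via the
`starts` argument. Test suites use 200–2000 runs; the emulated study's
20000 runs are reached by raising `n_runs`.

## Logistic model and screening

The published 3-variable model is shipped verbatim with V65 in percent
units (0–100): with fractional V65 the 0.028 slope would be an order of
magnitude too weak for the reported effect. Refits maximize the
Bernoulli likelihood via Newton iterations (statsmodels `Logit`);
complete separation is caught, coefficients are capped at ±50 with a
warning and a `separation` flag rather than silently diverging.
Univariate screening reports the Spearman rank correlation of each
covariate with the outcome (mid-ranks for ties, two-sided p from the t
approximation with n − 2 df); a per-covariate logistic fit is also
provided, since both conventions are used for "univariate analysis" in
the outcome-modelling literature.

## ROC machinery

AUC is the Mann–Whitney concordance with ties counted 0.5 (checked
against exhaustive pair counting); its 95% CI uses the Hanley–McNeil
standard error. The Youden cutoff maximizes sensitivity + specificity −
1 under the ≥ rule, ties broken toward the lowest cutoff (the more
sensitive rule). The paired model comparison is DeLong's Z-test for
correlated ROC curves, with the covariance from placement values;
identical score vectors give z = 0, p = 1 by convention. Stratification
partitions patients at NTCP ≥ cutoff; an empty group yields an undefined
(None) incidence, flagged rather than raised.

## Synthetic cohort generator

The generator emulates the cohort composition the models were designed
for, not any real patient set. Per patient:

- **DVH**: on a 1-Gy grid from 0 to 78 Gy, a mixture
  `(1−f)·falloff + f·plateau` of two normalized decreasing sigmoids. The
  fall-off midpoint ~ U(30, 60) Gy and width ~ U(5, 15) Gy model the
  bulk of the rectum; the plateau fraction f ~ U(0.05, 0.35) with edge
  midpoint at 76 − U(1, 5) Gy and width U(1, 3) Gy models the rectal
  wall adjacent to the prostate, which a small volume exponent makes
  influential. Curves are exactly 1 at 0 Gy and 0 at 78 Gy.
- **Covariates**: AH/AC ~ Bernoulli(0.667), acute GI ~ Bernoulli(0.417),
  independent of the DVH by default (an optional logit-scale slope links
  acute toxicity to V65); age ~ Normal(71.5, 8) clipped to [53, 85],
  giving P(age > 70) ≈ 0.57.
- **Outcome**: `late_gi ~ Bernoulli(NTCP)` under a configurable truth
  model. The LKB truth defaults to (D₅₀ = 87.3 Gy, m = 0.37, n = 0.10).
  The logistic truth keeps the published slopes and calibrates the
  intercept to −1.7468, the value at which the marginal late-toxicity
  rate under the default DVH/covariate distributions equals 25% (solved
  once by Brent root-finding on a 200,000-patient feature sample; with
  the published intercept the rate would be ≈ 33% because the synthetic
  V65 distribution, mean ≈ 28%, sits above the modelled cohort's).

Everything is a pure function of (config, seed).

**What the generator does not emulate.** Real DVH populations have
correlated shape features (planning constraints couple V65 to the
mid-dose region), acute toxicity genuinely depends on dose, and organ
motion perturbs the delivered dose; none of that is modelled. Passing
tests on synthetic cohorts therefore demonstrate the correctness of the
estimation machinery under the stated conditions, not clinical validity
of any fitted parameter set.

## Problem sizes and limitations

Test suites use cohorts of 120–500 patients, 50-replicate recovery
experiments, 200-run bootstraps and 10,000–20,000-patient calibration
cohorts; all sizes are module arguments, chosen as the smallest that
make the statistical checks sharp.

The main known limitation is intrinsic to the science: with D₅₀ well
above the maximum deliverable dose (~78 Gy), the probit model is
evaluated entirely in its extrapolated lower tail, and under the default
generator the true-model NTCP has a spread of only ≈ 0.02 (population
AUC ≈ 0.54). The (D₅₀, m, n) likelihood is then nearly ridge-shaped:
at 500 patients a sizeable minority of ML fits legitimately land on
boundary modes (n → 1 "mean dose" fits, m → 0 step fits, or D₅₀ → ∞
constant-probability fits) that beat the generating truth in likelihood.
Per-parameter means over replicates are therefore biased — the
volume-exponent recovery check in the test suite documents this
honestly rather than hiding it — while median fits, profile intervals
and bootstrap spreads remain informative. Users fitting real cohorts of
comparable size should expect the same behaviour and report profile
intervals, not point estimates alone.
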