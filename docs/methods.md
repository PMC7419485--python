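# Methods

## Data model

The unit of analysis is the dyad: a mother–infant pair observed in
coded play sessions. An event log row records one behavior in one
session (`dyad_id, group, month, session, code, duration_s,
occurrences`), with codes drawn from a fixed 26-name vocabulary — 15
infant behaviors (postures, locomotion, vocalization, three dyadic play
frames) and 11 maternal behaviors (handling, object mediation, speech,
touch). Sessions are pooled by month: the monthly value of a code is
the **sum** of that month's session values, under either encoding
(total seconds, or number of occurrences). Sum is the default rather
than mean because sessions are fixed-length windows, so the two differ
only by a constant factor; `aggregate_monthly(..., stat="mean")`
exposes the alternative.

Equal spacing is a modeling requirement, not a convenience: the lagged
regressions assume cotemporaneous, evenly sampled series. A dyad
missing an entire month therefore raises a hard error; the package
never imputes. Group labels are canonicalized case-insensitively and a
dyad may carry only one.

## Pooled VAR estimation

Each group × encoding cell gets its own VAR(p)

x(t) = c + Σⱼ B(j) x(t−j) + ε(t).

Pooling works by building lagged predictor rows **within** each dyad —
no lag pair ever spans a dyad boundary — and stacking them into one
design with a single common intercept per equation. Estimation is
per-equation OLS, which for an unrestricted VAR coincides with
multivariate least squares; with T monthly rows per dyad and D dyads,
the design has D·(T−p) rows and 1+p·m columns. The residual covariance
Σ uses the degrees-of-freedom-adjusted denominator rows − m·p − 1
(matching the convention of standard VAR software, which the test
suite verifies against statsmodels in the single-dyad case). Series
are not centered or scaled before fitting; raw monthly values are
preserved. Constant columns are an estimation error that names the
offending code, since they make the design rank-deficient.

Dyads are treated as exchangeable given their group: a common
coefficient set and common intercept, no per-dyad effects. This is the
minimal reading of pooling "across all infants"; per-dyad or
hierarchical VARs are deliberately out of scope, though the pooling
layer (`pooled_design`) isolates the place where they would plug in.

## Residual requirements and lag selection

A fitted model is admissible when its residuals behave like white
noise and the dynamics are stationary:

- **Serial correlation** — multivariate Portmanteau statistic with
  Ljung–Box small-sample weighting, Q = n² Σⱼ tr(Cⱼᵀ C₀⁻¹ Cⱼ C₀⁻¹)/nⱼ
  over lags j = 1..h, with residual autocovariances Cⱼ pooled within
  dyads (nⱼ = number of lag-j pairs); χ² with m²(h−p) df. Default
  h = min(8, rows/2).
- **Conditional heteroscedasticity** — multivariate ARCH-LM: regress
  vech(εₜεₜᵀ) on q within-dyad lags of itself; LM = ½·n·m(m+1)·R²ₘ
  with R²ₘ = 1 − 2·tr(Ω Ω₀⁻¹)/(m(m+1)); χ² with q·m²(m+1)²/4 df.
  Default q = 4.
- **Stability** — all companion-matrix eigenvalues strictly inside the
  unit circle.

Both tests are calibrated by Monte Carlo in the acceptance suite
(type-I error 0.05 ± 0.02 at n = 200, m = 2 over 1000 null
simulations). For the full 26-variable system on a 10-month panel the
ARCH-LM vech regression is infeasible (thousands of columns on ~135
rows); `diagnose` records such a test as *skipped with reason* rather
than failing the model, so the audit trail always says exactly what
was and was not checked. `select_lag` fits p = 1, 2, … and returns the
smallest admissible order together with the per-lag audit; failure to
converge by `p_max` raises an error carrying that trail.

The study pipeline defaults to a fixed p = 1 (the four-model design is
a lag-1 design), with `lag: auto` available.

## Orthogonalized IRFs and the conservative sweep

Impulse responses use the moving-average recursion Θ(0) = P,
Θ(h) = Σⱼ B(j) Θ(h−j), with P the lower-triangular Cholesky factor of
Σ under the chosen variable order. The shock is exactly one column of
P — one standard error of the orthogonalized innovation. The default
horizon is 10 steps (months). Two independent oracles pin the
implementation in the tests: the closed form B¹ʰ·P for p = 1, and a
shocked-minus-baseline noise-free simulation for general p, both to
1e−10; statsmodels' orthogonalized IRFs provide a third, external
check.

Ordering affects only P and the IRFs — coefficients and Σ are
ordering-invariant up to permutation, which the sweep re-verifies to
1e−10 on every run by refitting under each ordering. The conservative
convention reports variable j's impulse effects only from the ordering
placing j last, where its innovation is residualized on all other
variables; a full sweep is m orderings per model.

## Bootstrap bands

Confidence bands come from a residual bootstrap: draw innovation rows
with replacement from the pooled residual matrix (per-equation OLS
residuals are mean-zero by construction), rebuild each dyad's series
from its own first p observed months through the fitted coefficients —
so pseudo-data respect dyad boundaries — refit, and recompute the
IRFs. Default 100 replicates, pointwise percentile band at 95%
(percentile, not bias-corrected), widened where necessary to include
the point estimate so lower ≤ point ≤ upper holds everywhere.
Replicates that fail to re-estimate are dropped with a warning; more
than 20% drops aborts. One shared set of pseudo-panels serves all
orderings of a sweep, which is exact because re-estimation commutes
with column permutation. Coverage of a true-zero response is checked
by Monte Carlo (≈ 0.92 at 100 reps in the acceptance suite).

## Sign tables

A cell (response i, impulse j) is non-blank iff the band excludes zero
at some horizon in the scoring window, by default months 1–3 ahead;
its sign is the mean curve's sign at the *first* significant horizon.
A significant window containing both signs triggers a mixed-sign
warning (the rendering collapses to one sign by design). No
multiple-testing correction is applied across cells by default —
verdicts are per-cell at the band level — so sparse false positives at
roughly the test level are expected and are visible in the null cells
of synthetic runs. Combined group tables use the bracket dialect:
duration verdicts outside brackets, occurrence verdicts inside, each
tagged with the group initial (`+B[-G]`).

## Synthetic cohorts

The generator emulates the target study design: 15 dyads per group,
months 3–12, two 300 s sessions per month (20 sessions per infant
pooling to 10 monthly rows), all 26 codes. Each dyad's monthly latent
vector follows a stationary VAR(1) with group-specific coupling A,
intercept c, and innovation covariance Σ (spectral radius < 1 and
positive-definiteness are enforced), preceded by a 50-step burn-in so
the recorded window starts at stationarity; dyads are i.i.d. within
group. Default coupling is mild persistence (0.3 diagonal) plus two
mother↔infant channels signed oppositely in the two groups (+0.4 boys,
−0.4 girls), emulating the qualitative pattern of interest; defaults
c = 0, Σ = I.

Two emissions:

- `gaussian_latent` — the panel *is* the latent draw. The linear model
  is exactly correct, so parameter recovery can be tested sharply
  (±0.1 entrywise on 40-dyad × 40-month cohorts). These panels may be
  negative; the non-negativity invariant is enforced only on event-log
  and count/duration paths.
- `poisson_counts` — counts via a log-link Poisson (rate
  exp(1 + 0.5·x)); durations in session logs via softplus scaling
  (30 s per softplus unit). Realistic non-negative data for which the
  linear VAR is only an approximation — as it is for real coded
  behavior.

Session logs split monthly counts multinomially and durations equally
across sessions, so aggregation round-trips exactly. What the
generator does **not** emulate: coder noise and inter-rater
disagreement, occasional missing sessions, non-stationary developmental
trends across months, zero-inflation, and within-session dynamics.
Passing tests therefore certify the estimation machinery, not the
adequacy of a linear lag-1 model for any particular real cohort.

Closed-form ground-truth IRFs (Θ(0) = chol(Σ), Θ(h) = A·Θ(h−1)) are
available per group for convergence testing.

## Problem sizes and numerical choices

The test and acceptance suites run at deliberately chosen scales: the
emulated design itself (30 × 10 × 26) for structural checks with a
reduced 25-rep sweep smoke test; 4-variable, 40-dyad, 40-month
Gaussian cohorts (20-seed battery) for parameter recovery; n = 200
bivariate null panels (1000 simulations) for test calibration; 200
experiments × 100 reps for band coverage; and 20 end-to-end runs of a
5-variable, 30-dyad cohort with a +0.6 planted coupling for
sign-recovery. Tolerances: 1e−10 for all algebraic identities;
percentile interpolation is numpy's default; Cholesky failure on a
non-PD Σ is surfaced as an estimation error suggesting degenerate
residuals. Seeds thread through `numpy.random.SeedSequence` so every
run is bit-reproducible.

## Known limitations

- Granger-style, short-lag predictive relationships only: no
  structural VAR, vector error correction, fractional integration, or
  latent-variable (SSM/DSEM) extensions.
- Pooling assumes dyad exchangeability within group; no hierarchical
  shrinkage.
- The 26-equation system on 10-month panels is heavily parameterized
  (135 pooled rows vs. 27 columns per equation); asymptotic χ²
  approximations for the diagnostics are unreliable at that size, and
  the audit trail reports which checks could actually run.
- Sign tables inherit per-cell test error, matching the per-cell
  reporting convention. A false-discovery-rate layer (e.g.
  Benjamini–Hochberg) would need per-cell bootstrap p-values rather
  than percentile bands and is left as an extension.
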