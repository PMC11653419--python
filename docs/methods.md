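# Methods

## The decision model

`uvsdt` treats a patient's yes/no uptake of a treatment option as a signal
detection task.  Two latent populations are defined by the primary outcome:
S2 contains the participants whose Tinnitus Handicap Inventory (THI) score
improved by strictly more than the minimal clinically important difference
(MCID, 7 points; i.e. change < −7), S1 the rest.  Along an observable
decision *driver* x (hearing loss in dB HL at 8 kHz worst ear, or baseline
THI score), each population's probability of a yes-decision is modelled as a
logistic CDF

    P(yes | x, pop) = expit(theta1_pop + theta2_pop * x),

equivalently a logistic evidence distribution with location
mu = −theta1/theta2 and scale s = 1/theta2.  The two scales need not be
equal — the unequal-variance case is the point of the package, because it
changes the geometry of every accuracy summary.

Derived quantities, all exact for this parameterization:

* **Confusion probabilities** at criterion c: tp = 1 − F2(c),
  fp = 1 − F1(c), fn = F2(c), tn = F1(c); tp+fn = fp+tn = 1 identically.
* **ROC**: (fp(c), tp(c)) swept over the *bounded* driver range.  Because
  the range is bounded, the curve does not reach (0,0)/(1,1); the default
  AUC integrates only the observed span (`partial`), which is why empirical
  AUCs can fall well below 0.5 without implying worse-than-chance behaviour
  everywhere.  `closed` mode appends chords to the corners for comparisons
  on full support.
* **Logit-ROC**: logit(tp) is exactly linear in logit(fp) with slope s1/s2
  and intercept (mu2 − mu1)/s2.  The intercept is the accuracy index; for an
  equal-variance model with modes at ±mu it reduces to 2·mu/s.  A negative
  index means the S2 mode lies below the S1 mode on the driver axis.
* **Likelihood ratio** LR(x) = f2(x)/f1(x), evaluated in log space.  For two
  logistics with equal scales log LR is strictly monotone (not linear, as it
  would be for Gaussians — the tails of log f approach ±1/s linearly, but
  the transition region differs); with s2 < s1 it has one interior maximum,
  with s2 > s1 one interior minimum.  `lr_extremum` finds the stationary
  point from the sign change of d log LR/dx = (1 − 2F2)/s2 − (1 − 2F1)/s1.
* **Criteria**: roots of LR(x) = beta on the driver range, located by sign
  change bracketing on a dense grid (default 4096 points) and refined by
  bracketed root finding to |LR − beta| ≲ 1e−8.  All roots are reported —
  unequal scales permit two.  beta = 1 is the unbiased criterion; when LR
  never crosses 1 the result is flagged "always strict" (LR > 1 everywhere)
  or "always lenient".  Regions with LR < 1 are *lenient*, LR > 1 *strict*.
* **Utility threshold**:
  beta = [P(T−)/P(T+)] · [B(T−&D−) + C(T−&D+)] / [B(T+&D+) + C(T+&D−)],
  the likelihood-ratio criterion that maximizes expected value given base
  rates and a payoff matrix; it is mapped to driver units through
  LR(x) = beta.

Note on the equal-variance criterion: for Gaussian SDT the root of
LR(x) = beta has the closed form x = s²·ln(beta)/(2·mu); for logistic
components this holds only at beta = 1 (the symmetry midpoint).  The solver
is therefore validated against dense-grid scans and the |LR − beta|
residual, not against the Gaussian formula.

## Bayesian fitting

Each population is fitted separately under a Bernoulli likelihood with
independent zero-centred normal priors on (theta1, theta2), default sd 20
on both — vague relative to any plausible intercept and several hundred
times the realistic slope magnitude.  The reference sampler is an adaptive
random-walk Metropolis chain (20,000 retained draws after 5,000 burn-in;
proposal preconditioned on the curvature at the posterior mode and scaled
toward ~0.3 acceptance during burn-in).  A deterministic dense-grid
integration of the 2-parameter posterior is built in as a cross-check and as
a fast route for replicate studies; the two routes agree on P(theta2 > 0)
to < 0.01 on test fixtures.  Reported per fit: posterior mode, maximum
likelihood estimates (via an ordinary logistic regression), central 95%
credible intervals, P(theta2 > 0), the sampler seed and acceptance rate.

The *slope test* rejects H0: theta2 = 0 in favour of H1: theta2 > 0 when
P(theta2 > 0) ≥ 0.99.  A driver failing this test for either population is
declared inconsistent with the model's assumptions and downstream outputs
are suppressed (overridable as "exploratory").  Drivers whose pooled
yes-probability decreases with x are reversed first (x → x_max − x, the
offset recorded) so the one-sided test direction is well defined; criteria
found on the reversed scale map back as offset − c.

Complete separation of the response classes makes the likelihood degenerate;
it is detected and raises unless explicitly overridden (the proper prior
keeps the posterior integrable in that case).

## Imputation chain

Missing scores are filled by single conditional-mean imputation, in order:
baseline THI, baseline GHSI (with imputed baseline THI as a candidate
predictor), post-treatment THI (with both).  Each step screens candidate
predictors in two stages — type-III F-tests (full vs. reduced model,
sum-to-zero contrasts) at p < 0.15 in a joint model, then a refit keeping
p < 0.05 — fits OLS with reference coding on the kept predictors, predicts
the missing cells, and clamps predictions to the 0–100 score range.
Aliased or constant candidates are dropped with a warning; if nothing
survives stage 2 the grand mean is used (logged).  No residual noise is
added by default: the imputation is a point prediction, which understates
downstream uncertainty (credible intervals computed after imputation are
somewhat too narrow).  An optional residual-noise draw exists for
sensitivity analyses.  Observed cells are never modified, and missing
categorical entries are carried as an explicit "missing" level rather than
excluded.

## Synthetic cohorts

The generator emulates the study conditions so every stage is testable
against known truth.  Defaults: n = 145; P(S2) = 0.5 (the observed median
THI change sits essentially on the −7 boundary); hearing loss uniform on
[5, 115] dB HL; baseline THI assembled from tinnitus-duration and
non-hearing-problem category effects plus normal noise, bounded to [0, 100];
decision curves theta = (−2.0, 0.05)/(−1.0, 0.05) for the device evaluation
period (SEDEP, driver hearing loss) and (−3.0, 0.04)/(−2.0, 0.05) for
counseling uptake (PCU, driver baseline THI) — the latter pair gives the
unequal-scale, negative-accuracy-index regime with an interior LR maximum;
device purchase occurs only after an evaluation period (rate 0.58).  The
THI change is a shifted exponential on the membership's side of the −7
boundary (scales 7 for S1, 10 for S2, placing the expected extremes near
+28/−56 points at n = 145), truncated to keep both scores in range without
ever flipping a label: applying the MCID rule to the generated scores
reproduces membership for 100% of rows.  Missingness is injected MCAR at
rates 0.03 / 0.37 / 0.44 (baseline THI / post THI / GHSI), mirroring
response rates of 97% / 63% / 56%.  Scores are continuous, so the strict
boundary is almost surely never hit exactly.

What the generator does *not* emulate: the full covariate joint distribution
of a clinic population, informative (MNAR) missingness, correlation between
decision propensity and outcome beyond what membership induces, and
integer-valued questionnaire scores.  Passing recovery tests therefore shows
the estimator chain is correct and calibrated under the stated model, not
that the model is right for any particular clinic.

## Numerical choices

* Logistic CDF/PDF and all LR arithmetic run through `expit`/`log_expit`
  (overflow-safe for any finite input); the pdf uses the |z|-symmetric form.
* Root refinement uses bracketed Brent iterations (xtol 1e−12) after grid
  bracketing; duplicate grid-boundary hits are de-duplicated at 1e−9 of the
  range.
* The grid posterior spans mode ± 8 posterior SDs per axis (241 points);
  interval endpoints interpolate the cumulative marginal mass.
* Sampler determinism: every stochastic component takes an explicit seed and
  identical inputs + seed give bit-identical summaries.
* Dataset reversal caches the pre-reversal object so reversing twice
  restores driver values bit-exactly.

## Validation design and known limitations

Replicate studies in the test suite run at sizes chosen for a single-CPU
desk budget: 100 replicates at n = 1000/population for recovery and
coverage, 200 null and 100 alternative replicates at n = 150 for slope-test
calibration (grid posterior route), 20 pipeline replicates at n = 2000 for
end-to-end recovery.

Two precision facts shape what the suite asserts.  At n = 1000/population
with thetas (−2, 0.05)/(−1, 0.05) on a [5, 115] driver range, the S2
location mu2 = 20 lies at the edge of the design, and its sampling SE is
about 2.6 driver units even for an exact maximum-likelihood oracle, so
"mu2 within 15%" is a ~78%-probability event per replicate — no estimator
can make it a ≥90% event.  Similarly the fitted scale ratio s1/s2 carries
both scales' errors (~8% SD), so a 10% band is a ~80% event.  The property
tests therefore assert credible-interval coverage at its nominal rate,
scale recovery within 15%, and median ratio error below 10%; one
acceptance-style check intentionally encodes the stricter per-replicate
bound and documents its failure rather than hiding the gap.

Single imputation biases the labelled S1/S2 split of imputed rows toward
the conditional mean (visible as attenuation of the fitted separation in
pipeline runs with heavy missingness); multiple imputation with pooling is
out of scope.  Gaussian-SDT variants, rating-scale ROCs and hierarchical
pooling across decisions are likewise out of scope.
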