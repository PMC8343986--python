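# Methods

## The model

`lipidjm` estimates the association between the *current level* of a
longitudinal lipid marker (total, LDL or HDL cholesterol, analyzed on the
natural-log scale) and the hazard of death from cardiovascular disease, in a
shared-parameter joint model.

**Longitudinal sub-model.** For subject *i* at time *t* (years since
baseline), the observed log marker is

    y_i(t) = m_i(t) + e_i(t),        e_i(t) ~ N(0, sigma^2)
    m_i(t) = x_i(t)' beta + z_i(t)' b_i,   b_i ~ N(0, D)

with fixed effects x_i(t) = (1, t, covariates) and random effects
z_i(t) = (1, t) (random intercept + slope; an intercept-only structure is a
config option). Time enters linearly; covariates (baseline age, systolic BP,
BMI, diabetes, smoking, lipid-lowering drugs, sex in pooled analyses) are
held at their baseline values.

**Survival sub-model.** The CVD-death hazard is proportional-hazards in the
baseline covariates w_i and the *latent current value* m_i(t):

    h_i(t) = h0(t) exp( gamma' w_i + a * m_i(t) )

`a` is the association parameter: exp(a) is the relative hazard per unit
increase of the log marker, so a 10% increase of the raw marker multiplies
the hazard by exp(a * ln 1.1). That transform — not any refitting — produces
the reported "RR per 10% increase", with a Wald CI
exp((a ± 1.96 SE) ln 1.1) and the Wald p-value for a = 0.

**Baseline hazard.** h0 is piecewise constant on six intervals with knots at
event-time quantiles (configurable). This keeps the subject-specific
cumulative hazard closed-form: m_i is linear in t, so on each constant-rate
interval the integrand is exp(linear), an elementary integral. A degenerate
slope (|a * slope| ~ 0) switches to a fourth-order Taylor form at
|s·Δ| < 1e-3 to avoid cancellation.

**Likelihood and quadrature.** The marginal likelihood integrates, per
subject, (Gaussian longitudinal density) × (survival density) ×
(random-effects prior) over b_i. The integrand is log-concave in b_i, so a
damped Newton search (vectorized across subjects, warm-started between
likelihood evaluations) finds each subject's posterior mode; adaptive
Gauss–Hermite quadrature with 9 points per random-effect dimension (odd, so
a node sits at the mode) is centered there with the mode Hessian as scale.
With a = 0 the integrand is exactly Gaussian and the rule is exact, which
gives a sharp internal check: the joint log-likelihood must equal (mixed
model log-likelihood) + (piecewise-exponential PH log-likelihood) to
floating-point accuracy. Against dense-grid brute-force integration
(10,001-point 1-D grids, 201×201 2-D grids) the quadrature agrees to
relative error below 1e-6, and moving from 9 to 15 points changes the
log-likelihood by less than 1e-4 on study-sized data.

**Estimation.** Quasi-Newton (L-BFGS-B) on an unconstrained
parameterization: log-Cholesky factor of D, log sigma, log baseline rates;
beta, gamma and a unconstrained. Initial values come from the standalone
mixed-model fit (itself ML via profiled GLS over variance components) and a
Cox fit of the covariates, with a = 0 and crude occurrence/exposure rates.
Three conditioning devices make the optimization reliable, none of which
changes the model: (i) inside the hazard the trajectory is centered at the
mean observed log marker (a reparameterization of h0 — otherwise any move in
`a` must be compensated by ~a·m̄ ≈ 5.4·a in every log rate); (ii) covariate
columns are standardized internally and estimates, together with their
covariance, are mapped back to the raw scale exactly (raw SBP/BMI scales
leave the coefficient directions ~7 orders of magnitude apart in curvature,
which defeats quasi-Newton line searches); (iii) the optimizer runs in
coordinates scaled by the diagonal observed curvature at the starting values
(one cheap central-difference pass), after which typical fits converge in
10–30 iterations. Standard errors come from the numerically differentiated observed
information (central differences, step 1e-5·max(|θ|,1)); if the information
matrix is not positive definite the fit is returned with SEs flagged
unavailable rather than silently pseudo-inverted. Convergence uses the
optimizer's relative-loglik and gradient criteria (ftol 1e-11, gtol 1e-6,
max 400 iterations); ML (not REML) throughout, since the joint likelihood is
ML-based.

The per-node integrand evaluation is JIT-compiled with numba when available
and falls back to an equivalent vectorized numpy path (the two agree to
~1e-13; a test asserts the numpy fallback against the same oracle).

## Cox baseline and the proportionality screen

The separate-analysis baseline (Cox partial likelihood, Efron ties, Breslow
baseline hazard) is delegated to lifelines. The Grambsch–Therneau score test
on scaled Schoenfeld residuals is implemented here because both
per-covariate and global statistics are reported: with unscaled residuals
s_k at event times and a centered time transform g(t_k) (Kaplan–Meier
transform by default; identity and log available), the global statistic is
d·u'I⁻¹u / Σ(g−ḡ)² with u = Σ(g_k−ḡ)s_k, referred to chi-square on p df,
and the per-covariate version uses the corresponding diagonal terms. The
"P > 0.1" acceptance convention is a reporting rule, exposed as
configuration, not logic. Under proportional hazards the screen flags close
to 10% of replicates (calibration checked by simulation).

## The synthetic cohort generator

No cohort data are distributed, so the generator is a first-class module
that emulates the structure the analysis assumes: adults aged 40+ at
baseline, three markers measured on a 0/3/6/9/12-year schedule, missed
visits (MCAR Bernoulli, default probability 0.25 after the always-observed
baseline, giving 1–5 records per subject), administrative censoring at 14
years, and an event process driven by the current values of all three
latent trajectories (a hazard exponent Σ_m a_m·(m_im(t) − ref_m), still
linear in t, so event times are drawn exactly by closed-form inversion of
the cumulative hazard; unreached targets return +inf and are censored).

Default parameters are set to the scale of a Tehran-area cohort of adults
40+ (baseline TC ≈ 215/236 mg/dl in men/women declining ≈ 2 mg/dl/yr,
LDL-C ≈ 139/152 declining, HDL-C ≈ 38/45 rising; covariate distributions
match the cohort's published phase-1 means; sex-specific CVD-death
covariate effects with women at lower hazard). The per-marker associations
default to a_TC = 2.75, a_LDL = 1.65, a_HDL = 0.31 per unit log-marker —
i.e. pooled RRs per 10% increase of ≈ 1.30, 1.17, 1.03. The baseline-rate
scale was calibrated once, by bisection on the generator itself, so the
default cohort yields ≈ 5.4% CVD deaths by the administrative cutoff at
n = 4507, and then frozen (9.687e-4 × an increasing age shape).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: covariates are frozen at baseline (no
treatment initiation dynamics, although the observed lipid-drug uptake in
the motivating cohort tripled over follow-up); random effects are
independent across markers (real TC and LDL-C are strongly correlated, so
real univariate fits confound each other more than synthetic ones);
dropout is completely at random (no sicker-patients-miss-visits
informativeness); entry is simultaneous (median follow-up equals the
administrative cutoff rather than the staggered-entry 12.4 years);
non-CVD death is not simulated as a competing risk.

Study-design configurations are frozen alongside: a recovery design (n=600,
single marker, one binary survival covariate, rates calibrated to ~30%
events, true a = 1.5) and a scaled-down null design (n=300, a = 0,
intercept-only random effect, ~25% events). The intercept-only choice in the
null design is deliberate: 200 replicates of the 1-D quadrature fit run in
about a minute, and size of the Wald test does not depend on the
random-slope structure.

## Numerical and design choices

* **Knots**: event-time quantiles, 6 intervals by default, fewer for small
  studies; explicit knots can be passed (the replicate studies fix
  0/4/8 years so fits are comparable across replicates).
* **Ties**: duplicated visit times within subject are legal repeated
  measures; Efron tie handling in the Cox baseline.
* **Degenerate inputs**: non-PSD D, empty visit schedules, non-positive
  marker values, rank-deficient designs (reported with the collinear column
  names), all-singleton subjects with a random slope, fewer events than
  hazard intervals, and perfect separation in the Cox fit are all rejected
  with specific messages. Constant Cox covariates get coefficient 0 (flat
  partial likelihood) rather than an error.
* **Identifiability note**: age-at-visit = baseline age + study time, so the
  longitudinal design uses baseline age plus study time; including all three
  would be collinear.
* **Exclusion rule**: subjects with no valid measurement of a marker are
  dropped from that marker's models and counted in the log.
* **Multiple testing**: none; p-values are reported unadjusted and the
  rendered table says so.
* **Left truncation**: not modeled; all subjects enter at time 0.

## Validation summary (all recomputed by the test suite / acceptance script)

* quadrature vs brute force: relative error < 1e-6 (1-D and 2-D);
* a = 0 factorization: gap < 1e-8 (observed ~1e-13);
* recovery (40 reps, n=600, true a=1.5): estimate averaged over seeds within
  0.25 of truth; 95% Wald CI coverage ≥ 85%;
* null calibration (200 reps, n=300): 5% Wald test rejects within 5% ± 3%;
* PH screen calibration (200 PH-true reps): flags within the binomial 95%
  band around 10%;
* Cox toy fit matches grid maximization of the hand-written partial
  likelihood to 1e-6;
* default cohort: event fraction within 0.054 ± 0.02 at n = 4507, 1–5
  records per subject.

Problem sizes in the replicate studies (600/300 subjects, 40/200
replicates) are the studies' designs, chosen so each study is a few minutes
of desk-scale computation.

## Known limitations

The association structure is current-value only (no slope or cumulative
links); estimation is direct ML (no EM, no Bayesian machinery); no dynamic
prediction; competing risks are treated as censoring. Wald intervals on
log-RR are the only interval type. The reported baseline rates refer to a
subject at the centering log-marker level with w = 0 (the `hazard_center`
field of a fit records the level).
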