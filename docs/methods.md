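# Methods

## Pipeline overview

The package covers three layers: (1) synthesis of test data — LI tables
drawn from a latent two-factor measurement model, and raw bilateral CBFV
recordings with a known injected laterality; (2) signal preprocessing and
LI extraction with quality control; (3) statistics and confirmatory factor
analysis (CFA) of the resulting participants × 12 indicator table.

## The measurement model

Indicators are the six language tasks (A–F) at two sessions. For group
*g*, participant *i*, task *t*, session *s*:

x_tsi = mu_t + lambda_t1 f_1i + lambda_t2 f_2i + eps_tsi

with f1 ~ N(0, psi1) (psi1 free), f2 ~ N(0, 1) (fixed), orthogonal
factors, eps_tsi ~ N(0, theta_t) independent across sessions, and all of
mu, lambda, theta tied across sessions. Task D (Sentence Generation) is
the marker indicator: lambda_D = (1, 0) fixed. This yields the implied
moments mu~ = (mu, mu) and Sigma = Lambda diag(psi1, 1) Lambda' + Theta,
and free-parameter counts 18 / 23 / 36 / 46 for the one-factor,
two-factor, multigroup-shared-loadings and multigroup-free-loadings
variants. The factor covariance is fixed at zero throughout: the parameter
counts of the model family are only consistent with orthogonal factors
(adding factor 2 adds exactly its five free loadings).

### Estimation

Full-information maximum likelihood on raw rows: each row contributes the
marginal MVN deviance of its observed cells under the group's implied
moments. Rows are grouped by missingness pattern and summarized by
per-pattern sufficient statistics (count, mean, scatter), so one deviance
evaluation costs one Cholesky factorization per pattern. Degrees of
freedom use the raw-data convention (observed cells − free parameters);
each missing cell reduces df by exactly one.

The deviance is minimized by L-BFGS-B on a transformed parameterization
(log residual and factor variances — positivity without constraints) with
an analytic gradient assembled per missingness pattern via
dD/dSigma = n(S⁻¹ − S⁻¹(Scatter + dd')S⁻¹) and the chain rule through the
loading structure. Starting values are moment-based (marker-task
test–retest covariance for psi1, cross-covariances with the marker for
factor-1 loadings), plus seed-controlled jittered restarts (default 5).
When a nested model pair is fitted, the larger model receives an extra
start embedded from the smaller model's solution, which guarantees the
nested deviance ordering at the optimum. Convergence: L-BFGS-B with
ftol 1e-11 and gtol 1e-6; a non-positive-definite implied covariance
returns a large penalized value with a restoring gradient rather than
raising. Wald standard errors come from a central-difference Hessian of
the deviance at the optimum (Cov = 2·H⁻¹).

### Fit indices and model comparison

chi2_model = deviance − deviance(saturated), with the saturated model
estimated per group by EM for the incomplete-data MVN (closed form for
complete data; 90 parameters per group). The CFI baseline is an
independence model with free means and variances per indicator, no
equality constraints (24 parameters per group) — a conventional choice;
RMSEA uses sqrt(max(chi2 − df, 0)/(df·N)) with N the total row count and
no multigroup multiplier. Both conventions are choices among several in
circulation; the package's own comparisons (LRT, Mx AIC/BIC, Akaike
weights) do not depend on them. Mx conventions: AIC = deviance − 2·df,
BIC = deviance − df·ln N.

### Known behaviour of the 1-vs-2-factor LRT

Adding a factor is a non-regular comparison (the factor-2 contribution
lambda2·lambda2' has vanishing Jacobian at lambda2 = 0), and the
chi-square(5) reference is the conventional, not exact, null. In
simulation at n = 150 the test is mildly anti-conservative: the null
deviance-difference mean is ≈5.7 against the chi-square mean of 5, and the
empirical type-I rate is ≈6–8% at a nominal 5%. The calibration test
therefore uses 1500 null replicates so that its estimate (SE ≈0.6%) is not
dominated by sampling noise. Simulation sizes elsewhere: 100 recovery
tables and 40 power tables at n = 150 per group.

## Preprocessing choices

* **Epoch convention**: closed interval [−7, 27] s at 25 Hz → 851 samples;
  epochs overlapping the recording edge are dropped with a warning;
  adjacent epochs may overlap (34 s window vs 33 s inter-stimulus
  interval).
* **Range artifacts**: a trial is unusable when more than 5 samples in
  either channel fall outside mean ± 4·SD of that channel over the whole
  recording (configurable). The thresholds are explicit configuration, not
  a claim about any particular acquisition system.
* **Normalization** is recording-wide per channel (channel mean → 100), so
  the 60%/140% extreme-value thresholds keep one meaning across trials.
  The extreme-value screen is applied to normalized, heart-cycle-integrated
  values on the 100-centred (pre-baseline) scale, with strict
  inequalities (<60, >140).
* **Heartbeats** are detected on the mean of the two channels (the cardiac
  cycle is common to both; averaging halves noise), as local maxima
  separated by ≥0.4 s. Heart-cycle integration replaces samples in each
  inter-beat interval by the interval mean; samples before the first or
  after the last beat in an epoch take the nearest interval's mean without
  contributing to it; epochs spanned by fewer than two beats are flagged
  (reason `no-heartbeat`, an addition to the reason set so that every
  unusable trial carries exactly one truthful primary reason).
* **Period of interest**: default [6, 23] s peri-stimulus — the task
  occupies 3–23 s and the haemodynamic response lags onset by roughly
  3 s. Fully configurable and recorded in output metadata.
* **LI method**: mean of the averaged difference waveform over the POI
  (the peak method can induce artificial bimodality in LI distributions).
  SE is the SD of per-trial POI means over √n; the CI uses Student's t.
* **High-SE screen**: one-sided Hoaglin–Iglewicz with g = 2.2 (only
  unusually *high* trial-wise variability is suspect).
* **Exclusion rules**: cells with <10 usable trials are dropped; a task
  counts as excluded when either session is missing for quality reasons
  (not structural missingness); participants with >1 excluded task are
  removed. Re-running the rules on their own output changes nothing.

## The synthetic-data generator

`generate_li_table` draws directly from the measurement model: one latent
pair per participant shared by both sessions (residuals independent),
reflecting the session-tied model and the high test–retest reliability the
design assumes; missingness is completely at random (bounded at 20%).

`generate_recording` builds each channel as
baseline · (1 + pulsatility·pulse(t)) · (1 + response(t)/100) + noise:

* **Cardiac pulse**: asymmetric shape (≈60 ms systolic rise, 250 ms
  exponential decay) at 70 beats/min with ±5% uniform cycle-length jitter —
  enough pulsatile structure that heart-cycle integration has real work to
  do.
* **Haemodynamic response**: a trapezoid rising over 3 s after task onset,
  sustained through the 20-s task, returning over 5 s. The bilateral
  response amplitude defaults to 3% signal change, with the injected LI
  split as amplitude ± LI/2 between channels. Because normalization and
  baseline correction divide by slightly different channel means, the
  extracted LI is attenuated by ≈2·duty·amplitude/100 ≈ 4%; the default
  amplitude keeps the whole pipeline's round-trip error inside the 5%
  linearity tolerance rather than hiding the attenuation.
* **Default study configuration** (`default_study_config`): 31 left- and
  43 right-handers. Group means, factor variances and residual variances
  were set so the configuration reproduces the qualitative and
  quantitative pattern reported for this design: Welch t statistics of
  ≈3–5 for the four tasks that differ by handedness (B, C, D, E) and
  non-significant A and F; one-sample lateralization only for the speech
  production tasks (A, D) in left-handers; test–retest correlations in the
  0.5–0.9 range with task D strongest and task A weakest; larger
  between-subject variance in left-handers; and factor-2 loadings
  concentrated on the receptive tasks in left-handers only.

What the generator does **not** emulate: real spectral Doppler envelopes,
probe placement and insonation-depth effects, vessel anatomy, behavioural
responses, non-stationary heart rate, or mechanistically caused
missingness. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and decision rules under the stated signal model,
not robustness to every artifact a clinical recording can contain.

## Factor scores and outliers

Non-refined factor scores: per participant, sessions are averaged per task
and the score is the loading-weighted *mean* over tasks with data
(weights renormalized over present tasks), keeping scores on the LI scale
and robust to missing cells; negative loadings act as negative weights. A
factor whose included-task weights sum to ≈0 has an undefined score — a
real hazard when a group's factor-2 loadings are all near zero, in which
case the weighted mean is noise-amplified; interpret factor-2 scores only
when the loadings are substantively nonzero.

Outliers are flagged per group at more than 4× the group-mean Cook's
distance, computed from the OLS regression of the factor-2 score on the
factor-1 score (default) or, alternatively, from squared Mahalanobis
distance of the bivariate score (the "distance from the group average"
notion is ambiguous; both constructions are provided and neither is
claimed canonical). Cook's distances of a clean Gaussian cloud are
right-skewed, so a few flags per group (1–3 of 40) are expected behaviour,
not a defect — the screen is a visualization aid, not a test. The 95%
covariance ellipse uses the chi-square(2) quantile of the group's sample
covariance.

## Limitations

* The CFI/RMSEA baseline and sample-size conventions vary across SEM
  software; values are comparable within this package, not necessarily
  across packages.
* The LRT for factor count is anti-conservative at moderate n (above); at
  n ≈ 30–40 per group, model-selection outcomes lean on AIC weights, which
  inherit the same finite-sample behaviour.
* Factor-2 scores are contaminated by factor 1 when tasks load on both
  factors (an inherent property of non-refined scores, not of this
  implementation).
* Exact 25 Hz decimation requires the source rate to be an integer
  multiple of 25 Hz; other rates must be resampled upstream.
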