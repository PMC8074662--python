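# ftcdlat

Language lateralization from functional transcranial Doppler sonography
(fTCD): signal preprocessing, laterality-index extraction with quality
control, group statistics, and latent-factor modelling of lateralization
covariance in left- vs right-handed adults.

## The problem

fTCD measures cerebral blood flow velocity (CBFV) in the left and right
middle cerebral arteries while a participant performs language tasks. The
task-related left-minus-right velocity difference yields a **laterality
index (LI)** per participant, task and session (positive = left-hemisphere
dominance). With six tasks (A List Generation, B Phonological Decision,
C Semantic Decision, D Sentence Generation, E Sentence Comprehension,
F Syntactic Decision) measured twice, a central question is whether
lateralization is a single trait or several: does laterality on one task
predict laterality on all others (one latent factor), or do subsets of
tasks lateralize independently (two factors) — and does this structure
differ between left- and right-handers?

This package implements the full analysis chain for that question, for
researchers working with bilateral fTCD recordings or LI tables.

## The model

Twelve indicators (tasks A–F × sessions 1–2) load on one or two orthogonal
latent factors:

```
x_ts = mu_t + lambda_t1 * f1 + lambda_t2 * f2 + eps_ts,   s = 1, 2
f1 ~ N(0, psi1),  f2 ~ N(0, 1),  cov(f1, f2) = 0,  eps_ts ~ N(0, theta_t)
```

Loadings, task means and residual variances are tied across sessions.
Identification follows the marker convention: Sentence Generation (task D)
has loadings fixed at 1 (factor 1) and 0 (factor 2); factor means are 0;
factor 2's variance is fixed at 1. Free-parameter counts are 18 (one
factor), 23 (two factors), 36 (multigroup, loadings shared across
handedness groups) and 46 (multigroup, group-specific loadings).

Estimation is full-information maximum likelihood on the raw rows: each
participant contributes the marginal multivariate-normal deviance of their
observed cells, so missing LIs need no imputation. Models are compared by
likelihood-ratio tests, Mx-convention information criteria
(AIC = −2logL − 2·df, BIC = −2logL − df·ln N, with df = observed data
points − free parameters) and Akaike weights w_i ∝ exp(−ΔAIC_i/2).

Upstream of the model, raw recordings pass through: down-sampling to
25 Hz, epoching (−7 to 27 s peri-stimulus), rejection of trials with
multiple out-of-range samples, manual exclusions, normalization to a
channel mean of 100, heart-cycle integration, baseline correction
(−5 to 2 s) and a 60%/140% extreme-value screen. The LI is the mean
left-minus-right difference over the period of interest (mean method, not
peak), with a trial-wise SE, a t-based 95% CI and a reliably-lateralized
flag. Cells with unusually high trial-wise SE (Hoaglin–Iglewicz,
Q3 + 2.2·IQR) or fewer than 10 usable trials are excluded; participants
with more than one excluded task are dropped.

## Worked example

```python
import ftcdlat as fl

# synthetic study cohort: 31 left- and 43 right-handers
table = fl.generate_li_table(fl.default_study_config(seed=1))
left = table.group_values("left")

one, two, lrt = fl.fit_nested_pair(
    left, fl.build_spec(1, "single"), fl.build_spec(2, "single"), seed=0
)
print(f"one-factor : -2logL = {one.deviance:.3f}, df = {one.df}")
print(f"two-factor : -2logL = {two.deviance:.3f}, df = {two.df}")
print(f"LRT        : chi2({lrt['df']}) = {lrt['statistic']:.2f}, p = {lrt['p']:.3g}")

aics = [fl.mx_aic(f.deviance, f.df) for f in (one, two)]
w = fl.akaike_weights(aics)
print(f"Akaike w   : one-factor {w[0]:.2f}, two-factor {w[1]:.2f}")

rec = fl.generate_recording(2.0, fl.RecordingConfig(seed=5))
est = fl.compute_li(fl.preprocess_recording(rec))
print(f"round trip : injected LI = 2.0 -> extracted {est.li:.2f} "
      f"(95% CI {est.ci[0]:.2f}..{est.ci[1]:.2f}, {est.flag})")
```

Output:

```
one-factor : -2logL = 1302.021, df = 350
two-factor : -2logL = 1286.567, df = 345
LRT        : chi2(5) = 15.45, p = 0.00859
Akaike w   : one-factor 0.06, two-factor 0.94
round trip : injected LI = 2.0 -> extracted 1.93 (95% CI 1.92..1.93, left)
```

The left-handed cohort is generated from a two-factor configuration, and
the likelihood-ratio test recovers that: the two-factor model fits
significantly better, with an Akaike-weight probability of 0.94 of being
the better model of the pair. The signal round trip shows a noise-free
recording with a known 2.0% laterality passing through the whole
preprocessing chain to within the pipeline's linearity tolerance, with the
participant flagged as reliably left-lateralized.

A scikit-learn-style estimator wraps the same engine:

```python
cfa = fl.ConfirmatoryFactorModel(n_factors=2, multigroup=True,
                                 shared_loadings=False, seed=0).fit(table)
cfa.loadings_["left"]     # task x factor loading matrix
cfa.deviance_, cfa.df_    # -2logL and degrees of freedom
```

There is also a CLI (`ftcdlat simulate-table`, `preprocess`, `li`,
`stats`, `cfa`, `scores`) for running the stages over files; recordings
are tab-delimited `time_s / left / right / marker` files and LI tables are
CSV (`subject,group,site,A1..F2`).

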