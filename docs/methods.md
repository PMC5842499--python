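# Methods

This note documents the models and procedures implemented in `sharketho`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Signal model and feature extraction

Tri-axial acceleration is recorded at 30 Hz in units of g on the surge
(x), heave (y) and sway (z) body axes, optionally with 1 Hz depth and
temperature channels. Each axis is decomposed into

* **static** acceleration — the gravitational component reflecting body
  posture, estimated by a centred 3-s box smoother. At 30 Hz the window is
  `round(3 x 30) = 90` samples, forced odd to 91 so the estimate is
  symmetric. At the series edges the window shrinks to the available
  samples rather than padding with fabricated data.
* **dynamic** acceleration — the remainder (raw − static), so the
  decomposition conserves the raw signal to machine precision on every
  sample.

**ODBA** (overall dynamic body acceleration), the activity/energy proxy,
is `|dx| + |dy| + |dz|` per sample.

Tailbeat structure is measured on the dynamic sway axis by a continuous
wavelet transform with the complex Morlet mother wavelet (bandwidth 1.5,
centre frequency 1.0 in the `cmorB-C` convention). The frequency grid
defaults to 25 log-spaced bins over 0.2–10 Hz; both grid and wavelet
parameters are configurable because the original analysis software
publishes neither its scale set nor its amplitude normalisation. The raw
CWT modulus scales with wavelet scale, so the package calibrates a
per-frequency gain against unit-amplitude reference sinusoids at
construction time; after division, a pure sinusoid of amplitude *a* reads
back as *a* (verified against an FFT periodogram oracle, recovery within
10% and within one grid step in frequency). Per 1-s epoch the spectrum is
the mean modulus over the epoch's samples; the dominant cycle is the
argmax over the grid (ties to the lower frequency). Epochs with peak
amplitude below 1e-6 g carry no measurable oscillation and are flagged,
with the dominant frequency pinned to the lowest bin by convention.

The per-second feature table has 44 fixed columns — per-axis static and
dynamic means, mean ODBA, dominant-cycle amplitude (`Amp`) and frequency
(`Hz`), and SD/skewness/kurtosis/max/min of the seven signals (three
static, three dynamic, ODBA) — plus one amplitude column per wavelet bin
(69 columns at the default grid). Skewness is the sample g1 and kurtosis
the excess kurtosis; both are defined as 0 (not NaN) on constant epochs.
`Amp`/`Hz` are per-epoch dominants rather than means; the alternative
reading (per-second means of an upstream dominant track) was rejected
because the dominant-cycle definition is the only one the CWT gives
directly per epoch.

## Labels, datasets and the split

Behaviour annotations (start, end, behaviour) are rasterised onto 1-s
epochs aligned to the series start. Unannotated seconds take the swim
background. A partially covered second takes the behaviour covering at
least half of it; coverage ties break to the earlier annotation, and when
two annotations fully cover an epoch the later-starting one wins. Trailing
partial seconds are dropped.

The labelled data are split 60/20/20 (train/validation/test) by
stratified sampling with per-class largest-remainder allocation, so every
split's class counts are within one observation of exact proportionality.
Class members are put in a canonical content-based order before the
seeded shuffle, making the split a function of the data multiset rather
than row order. Classes with fewer than three members go entirely to
train, with a warning. Features are z-scored with training-set statistics
before logistic-regression and neural-network fitting (both learners are
scale-sensitive; the tree learners receive raw features).

## Base learners and the voting ensemble

Five scikit-learn base learners, all probability-emitting:

| kind | model | fixed settings | open settings chosen here |
|------|-------|----------------|---------------------------|
| LR   | one-vs-rest logistic regression | — | L2 penalty, C = 1, max 1000 iterations |
| ANN  | multilayer perceptron | 1 hidden layer x 100 nodes, softmax output | ReLU activation, max 500 iterations |
| RFG  | random forest, Gini split | probability = mean of per-tree probabilities | 100 trees, sqrt(p) features per split |
| RFE  | random forest, entropy split | differs from RFG only in criterion | same |
| GB   | gradient tree boosting | 100 trees, max depth 3 | deviance loss, learning rate 0.1 |

The voting ensemble averages the members' class-probability matrices with
per-member weights normalised to sum one, and predicts the argmax class
over the canonical order `[swim, headshake, rest, chafe, burst]`; exact
ties break to the earlier class. Members are ranked on validation macro-F;
all members clearing a configurable floor (default 0, keeping all five)
are retained and the best performer is weighted 3, the rest 1 — the
others must therefore agree confidently to override it.

## Evaluation metrics

Per class: precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F the harmonic
mean, class error `FN/(TP+FN) = 1 − recall`; overall: the macro-averaged
F (unweighted mean of per-class Fs, equal weight to rare behaviours).
Macro-F averages **unrounded** class Fs; rounding happens only at report
time — this is what makes the shipped reference values reproduce exactly
at 3 dp. Zero-support classes contribute F = 0 (conservative). The six
reference test-set confusion matrices ship as integer CSV fixtures with a
SHA-256 manifest checked on load.

## From classified seconds to foraging records

Headshaking proxies successful prey capture. Predicted headshake runs
shorter than 2 s are relabelled to swim (observed headshakes always
lasted at least 2 s). Relabelling, rather than deleting, keeps the
timeline contiguous for hourly binning; the filter is idempotent and can
only remove presence-hours, never add them. Behaviour is then reduced to
presence/absence per clock hour; hours partially covered at deployment
edges are kept if at least 30 min is recorded.

Tidal phase comes from a station peak table: local peaks lag the station
by 1 h (configurable), High/Low are the +-1 h windows around the shifted
peaks, and Flood/Ebb fill the rising/falling stretches between, so phases
partition the covered timeline. Season is wet (April–September) or dry
(October–March). Collinearity among candidate covariates is screened with
generalized variance-inflation factors (Fox–Monette determinant ratio);
the score thresholded at 3 is `GVIF^(1/df)` — the square of the
df-adjusted value, i.e. on the ordinary-VIF scale — and the worst
offender is removed iteratively.

## The presence model

Hourly presence is modelled on the logit scale as intercept + cyclic
cubic spline of hour-of-day + tide factor (reference Ebb) + season factor
(reference wet) + per-individual intercept. Implementation choices:

* **Cyclic smoother.** Basis dimension 8 (7 centred columns), built on a
  domain augmented with 0 and 24 so the cyclic constraint enforces
  f(0) = f(24) with period exactly 24 h. Basis and curvature penalty come
  from statsmodels' cyclic cubic spline machinery.
* **Random intercept.** Realised as a ridge-penalised block of individual
  dummies — the standard mixed-model representation of a Gaussian random
  intercept. Full mixed-model machinery is not required at this scale
  (tens of individuals); the reported random-intercept variance is the
  empirical variance of the estimated intercepts.
* **Fitting.** Penalised IRLS with block penalty
  `lambda_s * S_spline (+) lambda_b * I`. Both penalties are selected by
  maximising a Laplace-approximate restricted marginal likelihood over a
  log-spaced grid (10 points over 1e-2–1e4 for the smoother, 7 over
  1e-2–1e2 for the intercepts). Pointwise 95% bands use the Bayesian
  posterior covariance `(X'WX + S)^{-1}`; smoother edf is the trace of
  the corresponding block of the hat matrix.
* **Degenerate inputs.** A single-level outcome or a single individual is
  an error; if a parametric coefficient exceeds 10 on the logit scale the
  fit warns of quasi-separation and refits with a small ridge (1e-2) on
  the parametric block.
* **Model selection.** Candidate covariate sets (the seven
  hour/tide/season combinations by default) are ranked by log-likelihood
  closest to zero. Because each individual is deployed in a single
  season, the *conditional* likelihood lets the penalised intercepts
  absorb a dropped season effect and mis-ranks candidates; the ranking
  therefore uses the Laplace-approximate **marginal** log-likelihood (the
  quantity mixed-model software reports as the model log-likelihood),
  with the conditional value also tabulated. Under this criterion the
  full generator model ranks first on simulated studies.
* An adjusted R² is reported as deviance-explained corrected for the
  model's effective degrees of freedom.

## Synthetic data generator

The generator is first-class, tested code; it defines the study
conditions for every end-to-end check.

**Ethogram sessions.** Swim is the background; events (chafe 0.40, burst
0.30, prey-manipulation 0.20, rest 0.10 by weight) are interleaved
between swim bouts, giving a swim-dominated mix with rare burst and
headshake seconds, echoing captive-trial class frequencies. Bout
durations are truncated normals on the observed ranges (rest 73.3 s SD
107.4, range 12–291; chafe 4.6 s SD 1.6, range 3–11; burst 1.3 s SD 0.5,
range 1–3; headshake runs at least 2 s). Because truncation of an
asymmetric range shifts the mean, the underlying location is solved so
the truncated mean equals the observed mean. Prey-manipulation windows
contain one or more headshake runs separated by swim gaps, mirroring the
intermittent structure of real prey handling.

Signal shapes are stylised: swim is a 0.5–1.5 Hz sway sinusoid
(amplitude 0.1–0.3 g) with gravity on the heave axis; rest is static
gravity with 0.005 g noise; burst is 2.5–5 Hz sway at 0.7–1.5 g with a
strong surge component; headshake is 2–4 Hz sway at 0.8–1.8 g with
minimal surge; chafe rolls the gravity vector from heave into sway and
back with moderate 1–2 Hz dynamics. The headshake and burst bands
deliberately overlap so the classification task is non-trivial; the
surge fraction and amplitude distributions are what separate them. All
parameters are exposed in `DEFAULT_BEHAVIOUR_PARAMS`. No published
amplitude statistics exist per behaviour, so these values are the
package's own stylisation; mean-ODBA ordering
rest < swim < {chafe, headshake, burst} is enforced by test.

**Wild deployments.** Hourly headshake presence follows a Bernoulli
process whose logit is intercept 0.576 + cosine diel curve (amplitude
1.0, peak 17:00) + tide effects (Flood 0.012, High −0.600, Low 0.028,
reference Ebb) + dry-season −0.868 + per-individual N(0, 0.3²)
intercept; the factor effects are the field-study point estimates, the
diel amplitude a stylised choice consistent with a pronounced evening
peak. A standard study is 20 individuals (half wet season, half dry) x
120 h, i.e. 2400 hourly records. Tide peaks follow the 12.42-h
semidiurnal period. Present-hours of a full signal-level deployment
receive one to three prey-manipulation events; the 30-Hz channels are
synthesised in float32, hour by hour, to bound memory at 120-h scale.

**What the synthetic tests do not show.** The generator has no ocean
surge noise, no gliding, no posture drift, stationary within-bout
frequency content and exactly known class boundaries; real tag data are
harder on every one of these axes. Passing end-to-end checks therefore
demonstrates that the pipeline's machinery is correct and well-calibrated,
not that its field performance equals the synthetic numbers.

## Problem sizes used by the shipped checks

End-to-end classification uses two independent 2400-s sessions (one for
training/validation/test splitting, one held out entirely); parameter
recovery uses 20 independent studies of 2400 hourly records each. These
sizes give stable statistics while keeping the default check runs short.

## Known limitations

* The ridge-penalised intercept is an approximation to a full
  mixed-model random intercept; variance components are not reported
  with uncertainty.
* Model ranking uses a Laplace approximation to the marginal likelihood;
  like REML-type criteria it is only approximately comparable across
  fixed-effect structures.
* The classifiers ignore serial dependence between consecutive seconds;
  the 2-s run filter is the only temporal post-processing.
* The wavelet amplitude calibration assumes locally sinusoidal signals;
  strongly transient events read back slightly low.
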