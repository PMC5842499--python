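# sharketho

Behaviour classification and foraging-pattern analysis for tri-axial
shark accelerometry.

Archival acceleration data loggers (ADLs) record body movement of
free-ranging sharks at 30 Hz, but the behaviours themselves — routine
swimming, resting, chafing, burst-swimming and the side-to-side
headshakes that accompany prey capture — must be inferred from the
signal. `sharketho` implements the full chain from raw tag export to
ecological inference for biologging studies of this kind:

1. **Features.** Each axis is split into static (posture, 3-s box
   smoother) and dynamic (movement) components; overall dynamic body
   acceleration is `ODBA = |dx| + |dy| + |dz|`; tailbeat frequency and
   amplitude come from a complex-Morlet continuous wavelet transform of
   the dynamic sway axis. Per-second feature vectors combine means, SDs,
   skewness, kurtosis, extrema and wavelet-bin amplitudes (69 features
   at the default grid).
2. **Classifier.** Five probability-emitting base learners — one-vs-rest
   logistic regression, a 100-node single-hidden-layer perceptron, Gini
   and entropy random forests, and gradient boosting (100 trees, depth
   3) — are trained on a stratified 60/20/20 split and combined by a
   *voting ensemble*: a weighted average of class-probability matrices
   (best validation performer weighted 3x) with argmax prediction.
3. **Evaluation.** Per class *i*:
   `Re = TP/(TP+FN)`, `Pr = TP/(TP+FP)`, `F = 2·Pr·Re/(Pr+Re)`, and the
   macro-averaged F `= (1/M) Σ F_i`; class error `= 1 − Re`. Reference
   test-set confusion matrices for all six classifiers ship as fixtures.
4. **Foraging analysis.** Headshake runs under 2 s are filtered out,
   presence is binned per clock hour, tide phase (Ebb/Low/Flood/High)
   and season (wet/dry) are attached, collinear covariates are screened
   by generalized variance-inflation factors, and hourly presence is
   modelled with a binomial GAMM: a cyclic hour-of-day smoother
   (period 24 h), tide and season factors, and per-individual
   intercepts.
5. **Simulation.** A generator produces labelled ethogram sessions and
   multi-day "wild" deployments with known diel/tidal/seasonal foraging
   structure, so every stage is testable without any field data.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Train on one simulated session, classify an independent one, and model a
simulated multi-shark study:

```python
import sharketho as se
from sharketho.metrics import confusion, metrics
from sharketho.simulate import simulate_ethogram_session, simulate_study

# -- classify -----------------------------------------------------------
series_tr, labels_tr = simulate_ethogram_session(total_s=2400, seed=11)
series_te, labels_te = simulate_ethogram_session(total_s=2400, seed=99)

data = se.LabelledDataset(se.extract_features(series_tr), labels_tr)
train, val, test = se.stratified_split(data, (0.6, 0.2, 0.2), seed=3)
ens = se.select_members(se.train_all(se.default_specs(0), train), val)
report = metrics(confusion(labels_te.labels, ens.predict(se.extract_features(series_te))))
print(report.summary())

# -- model hourly foraging ---------------------------------------------
records = simulate_study(n_sharks=20, seed=1)
result = se.fit_presence_model(records, formula=("hour", "tide", "season"))
print(result.summary())
```

The classification report prints per-class TP/FP/FN, precision, recall
and F plus the macro-averaged F (1.000 for this fully separable synthetic
pair — real tag data are substantially harder; the suite's acceptance
bound is macro-F >= 0.80). The presence-model summary prints:

```
Binomial presence model (logit link)
  terms: hour + tide + season + individual intercepts
  observations: 2400, individuals: 20
  log-likelihood (marginal): -1499.806   conditional: -1465.890   deviance: 2931.779
  adj. R-squared: 0.1113

Parametric coefficients:
              coef     SE      z
Intercept    0.657  0.121  5.421
tide[Flood]  0.053  0.144  0.367
tide[High]  -0.781  0.152 -5.128
tide[Low]    0.095  0.149  0.635
season[dry] -0.989  0.131 -7.545

Smoother s(hour): edf 3.92, peak at 17.3 h
Individual intercept variance: 0.0332
```

The generator's true effects were High −0.600, dry −0.868 and a diel
peak at 17:00: the fit recovers the signs, approximate magnitudes, and
the evening foraging peak within half an hour. Fewer successful
predations over high tide and in the dry season is exactly the pattern
this modelling stage is designed to expose.

A `sharketho` command-line tool wraps the same stages
(`simulate`, `features`, `split`, `train`, `predict`, `evaluate`,
`filter`, `bin`, `model`); `sharketho evaluate --fixtures` prints the
full reference metric report.

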