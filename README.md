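# donorscreen

Automated screening of potential organ donors from ICU laboratory time
series.

Between 30% and 60% of potential organ donors are never identified or
referred to an organ donation organization, largely because
identification relies on busy clinicians recognizing a rare event
(~2% of ICU stays). `donorscreen` implements a screening pipeline that
flags potential donors from data every hospital already has: timestamped
laboratory results over the last 72 h of a stay, the responsible medical
specialty, and whether head imaging was ordered.

## The model

The final 72 h of each stay are gridded into 9 blocks of 8 h (last value
per block), imputed by last-value-carried-forward and then by draws from
a Gaussian whose central 95% interval equals each analyte's
physiological normal range, and z-standardized. Two models are trained
and compared:

* **NN** — a temporal convolutional autoencoder (convolutions slide only
  along the time axis; trained to reconstruct non-donor patients only,
  so it also behaves as an anomaly detector) embeds each patient's
  analyte × block grid into a latent vector; a four-layer classifier
  with a sigmoid output consumes the latent plus the two static
  variables, trained with class weights `n_non_donor / n_donor`.
* **LM** — weighted logistic regression on the last (block-9) value of
  every analyte plus the same statics: identical information at the
  final time point, none of the temporal history.

Evaluation follows the reference screening protocol: AUROC and scaled Brier score with
95% percentile bootstrap CIs (2000 resamples of the untouched test set),
paired bootstrap Z tests between models on shared resamples, calibration
curves, and an operating cutoff derived by threefold cross-validation on
the training data to target 90% sensitivity. Secondary analyses evaluate
the frozen models 8/24/48 h before the end of stay and retrain after
removing progressively less-rare laboratory analytes.

Because real screening cohorts are access-restricted, the package ships
a seeded synthetic ICU cohort generator (2% prevalence, ~100 analytes
with normal ranges, missing-not-at-random ordering, end-of-stay drift in
donor-like patients) so the entire pipeline is testable end to end. See
`docs/methods.md` for the full model description and the generator's
scope.

## Worked example

```python
import donorscreen as ds

model = ds.DonorScreeningModel.from_simulation(
    ds.SimConfig(n_patients=2000, signal_shape="transient", seed=7)
)
res = model.fit()
print(res.summary())
```

```
Donor screening results (test partition)
========================================================
n test = 66   prevalence = 0.106

                          NN model        Logistic model
auroc          1.000 (1.000-1.000)   0.910 (0.730-0.996)
scaled_brier   0.929 (0.757-1.000)  0.182 (-0.787-0.689)
sensitivity    1.000 (1.000-1.000)   0.875 (0.500-1.000)
specificity    0.983 (0.946-1.000)   0.867 (0.774-0.946)
cutoff nn       0.061
cutoff lm       0.001

paired AUROC z = +1.33, p = 0.184
paired scaled-Brier z = +1.62, p = 0.105
```

Reading the output: this cohort carries a *purely temporal* signal —
donor trajectories drift over the final 48 h but return to baseline
before discharge, so the last values alone are nearly uninformative.
The temporal NN separates the 7 test donors from the 59 non-donors
perfectly, while the last-value logistic model reaches AUROC 0.91
(mostly through the static predictors and drift residue), with a wide
bootstrap CI over only 66 test stays; at these sizes the paired Z test
cannot yet call the difference significant. The cutoffs were derived
from training data only, aiming at 90% sensitivity. With the default
`signal_shape="monotone"` the drift persists to the end of stay and
both models discriminate near-perfectly, as expected when the final
values carry most of the signal.

Secondary analyses hang off the results object:

```python
res.prospective((8, 24, 48))       # frozen models, earlier anchors
res.rare_lab_ablation((0.1, 0.2))  # retrain at coarser panels
res.subgroup_aurocs                # per donor subtype
res.save_artifacts("out/")         # metrics.json, predictions.csv, ...
```

The same pipeline is scriptable from the shell:

```bash
donorscreen simulate --seed 7 --outdir out           # labs/stays/panel CSVs
donorscreen run-all  --seed 7 --outdir out           # full protocol
donorscreen prospective --seed 7 --outdir out --horizons 8,24,48
```

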