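# prexstim

Preoperative-EEG prediction of vagal nerve stimulation (VNS) response in
drug-resistant epilepsy: a tested re-implementation of the Pre-X-Stim
pipeline as a reusable Python library with a thin command-line interface.

About half of implanted VNS patients obtain a substantial (>= 50%)
seizure reduction, but responders cannot currently be identified before
surgery.  The predictor implemented here needs nothing beyond a routine
preimplantation scalp EEG recorded during a standard eight-condition
activation protocol (rest, eyes opening/closing, photic stimulation,
hyperventilation).  It is aimed at clinical-neurophysiology researchers
who want to apply, audit or extend the method — including applying a
model trained on one EEG system to recordings from another.

## The method

For each of the 19 electrodes of the 10-20 montage and each standard band
(theta 4-7.5, alpha 8-12, beta 14-30, gamma 31-45 Hz), the EEG is
transformed into a power envelope |z(t)|^2 via the Fourier/analytic-signal
construction, averaged within each protocol condition, and normalized to
the first rest interval:

    RP(channel, band, condition) = mean envelope power in condition
                                   ---------------------------------
                                   mean envelope power in Rest #1

Eight fixed electrode-group averages of RP — e.g. right-frontal beta
during eyes opening/closing, central gamma during hyperventilation — form
the feature vector x, classified by two-class LDA with pooled covariance
(w = Sigma^-1 (mu_resp - mu_nonresp)).  Validation follows the two
published schemes: a single classifier trained on all n training
subjects, or majority voting of the n leave-one-out fold models.

Recordings from a different EEG system are first *harmonized*:
re-referenced to the training montage (average of Fz, Fp1, Fp2 ~ AFz) —
which cancels the original reference exactly, whatever it was — then
anti-alias filtered and resampled to 128 Hz.

Because the original patient EEG is not redistributable, the package
ships a synthetic protocol-EEG generator with known class effects
(band-limited noise carriers, condition modulation, planted responder
reactivity, pink background, both recording dialects), so the entire
chain is testable end to end against closed-form expectations.

## Worked example

`examples/evaluate_published_outcome.py` evaluates the published
external-validation outcome (eight subjects on a second recording system;
six real-life responders of whom the model missed two, both
non-responders correct):

```
confusion: TP=4 FP=0 FN=2 TN=2
accuracy 75%, sensitivity 67%, specificity 100%

age at epilepsy onset: median 16, range 7-60
valproate use: 5 of 8 subjects
levetiracetam vs 36/60 in training: Fisher p = 0.001
valproate vs 14/60 in training: Fisher p = 0.034
```

Accuracy is (TP+TN)/8; sensitivity TP/(TP+FN) = 4/6 rounds to 67%;
specificity TN/(TN+FP) = 2/2.  The Fisher p-values compare drug use
between the training and validation cohorts.

The remaining examples each exercise one capability: `simulate_cohort.py`
(write a synthetic EDF cohort), `extract_features.py` (full signal
pipeline on one subject, with the generator's closed-form expectations),
`cross_system_invariance.py` (the same sources rendered as 1000 Hz
vertex-referenced and 128 Hz AFz-referenced recordings yield features
agreeing to < 0.01%), `train_and_validate.py` (both validation schemes on
a simulated 35/25 cohort), and `stepwise_selection.py` (the leave-one-out
stepwise selection procedure recovering planted predictors).

The same workflow is available from the shell:

```sh
prexstim simulate --out cohort/ --seed 7 --n-responders 35 --n-nonresponders 25
prexstim features --edf-dir cohort/ --out features.tsv
prexstim train --features features.tsv --out model.json
prexstim predict --model model.json --train-features features.tsv \
                 --features validation.tsv --mode voting --out pred.tsv
prexstim evaluate --predictions pred.tsv --truth truth.tsv
```

## Layout

- `src/prexstim/` — the library: `eeg_io` (EDF+/event I/O), `preprocess`
  (re-reference/filter/resample), `bandpower` (envelopes, protocol
  segmentation), `features` (relative power, the eight predictors),
  `model` (LDA, validation schemes, stepwise-LOO selection), `evaluation`
  (metrics and cohort statistics), `synth` (the generator),
  `experiments` (reproducibility experiments), `cli`.
- `docs/methods.md` — the model, its assumptions, parameter defaults and
  limitations.
- `examples/` — one narrative script per capability.
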