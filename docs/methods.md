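# Methods

## The prediction problem

Roughly half of drug-resistant epilepsy patients implanted with a vagal
nerve stimulator (VNS) obtain a substantial (>= 50%) seizure reduction,
but responders cannot currently be identified before surgery.  The
predictor implemented here uses only a routine preoperative scalp EEG
recorded during a fixed eight-condition activation protocol: how strongly
a patient's band power *reacts* to eyes opening, photic stimulation and
hyperventilation — relative to initial rest — carries information about
later VNS response.

The pipeline is: raw 19-channel EEG (10-20 montage) -> harmonization
across recording systems -> band-power envelopes -> per-condition relative
power -> eight fixed electrode-group features -> two-class linear
discriminant analysis (LDA), validated either as a single classifier or as
a majority vote of leave-one-out fold models.

## Harmonization across recording systems

Training data came from a 128 Hz system referenced to AFz, which sits at
the centroid of Fz, Fp1 and Fp2 and is modelled as their average;
validation data from a 1000 Hz system referenced to the vertex average
(Fz, Cz, Pz).  Because any reference enters every channel as a common
additive term, re-referencing to the target montage,

    v_i' = v_i - mean(v_Fz, v_Fp1, v_Fp2),

cancels the original reference exactly, whatever it was.  This linear
identity is the entire basis for cross-system portability, and the test
suite asserts it directly (re-referencing from any starting reference
yields identical signals to float rounding).

Filtering and resampling (choices the source material leaves open):

* **Anti-alias low-pass**: zero-phase symmetric FIR (Kaiser design, 60 dB
  stopband), passband edge at 0.9x and stopband edge at 1.25x the cutoff;
  default cutoff 56 Hz before 1000 -> 128 Hz conversion.  This preserves
  the gamma band (<= 45 Hz) to within 0.1% while attenuating everything
  aliasable at the 64 Hz Nyquist by >= 60 dB.  The filter is applied once,
  centered, so it is exactly zero-phase.
* **Resampling**: rational polyphase (16/125 for 1000 -> 128 Hz), so there
  is no cumulative timing drift.
* **Drift removal**: optional zero-phase order-2 Butterworth high-pass at
  0.5 Hz (default on), applied after resampling — the operations are
  linear, so the order is immaterial for sub-Nyquist content, and it is
  eight times cheaper at 128 Hz.  Its response at the lowest analysis
  frequency (4 Hz) deviates from unity by < 0.1%.

## Band power and relative power

Each channel is transformed into four band-power envelopes — theta
(4-7.5 Hz), alpha (8-12 Hz), beta (14-30 Hz), gamma (31-45 Hz) — by a
fused Fourier band-pass / analytic-signal construction: take the DFT of
the whole recording, zero every bin outside the band and all negative
frequencies, double the retained bins, and invert.  The squared magnitude
of the resulting complex signal is the instantaneous band power (uV^2);
for a pure in-band tone of amplitude A it equals A^2.  Band edges are
inclusive; no windowing or segmenting is applied before the transform
(edge effects are confined to roughly the first and last second, which
fall inside the two-minute opening and closing rest blocks).

Envelopes are averaged within the eight protocol conditions (nominal
durations 120, 10, 10, 150, 240, 10, 10, 120 s; segment boundaries are
event onsets rounded to samples, half-open ranges) and each condition mean
is divided by the Rest #1 mean of the same channel and band.  The
resulting *relative power* is dimensionless, equal to 1 under no
reactivity, and exactly invariant to any overall amplitude scaling of the
recording.  The printed photic sub-schedule (5 -> 30 -> 5 Hz flash trains)
is carried as metadata only; condition 4 is analyzed as a single interval.

Two readings of the source protocol were settled as follows: "power
envelope" is taken as the squared analytic magnitude (not the magnitude);
and of the two eyes-opening/closing blocks the first (condition 2) feeds
the two eyes-O/C features by default, configurable to the second
(condition 6).  The features are ratios, so monotone redefinitions of the
envelope largely cancel.

## The eight features and the classifier

The eight predictors are fixed (electrode group, condition, band) cells —
right-frontal beta and theta around eyes-O/C and Rest #2, posterior-
quadrant alpha/beta under eyes-O/C and hyperventilation, central gamma
under hyperventilation, right-anterotemporal theta in the closing rest —
each computed as the unweighted mean of relative power over its
electrodes.  The set ships as a constant and is never silently replaced
by re-derived selections.

The classifier is two-class LDA: class means, pooled within-class
covariance with the unbiased n-2 denominator, and a Gaussian posterior
with configurable priors (empirical class frequencies by default; the
source material does not state which convention was used).  A posterior
of exactly 0.5 predicts non-responder — the conservative choice of not
promising treatment benefit on a tie.  If the pooled covariance is
numerically singular a ridge of 1e-6 * trace(S)/p is added automatically.

Validation schemes mirror the two published approaches: (A) one model
fitted on all n training subjects; (B) n leave-one-out fold models voting
on each validation subject, majority rule, with even-split ties broken by
the sign of the mean fold discriminant score (deterministic, and uses the
ensemble's pooled evidence).  Scheme B's per-subject vote counts are
retained for auditing.

The original feature selection — forward-backward stepwise logistic
regression run within every leave-one-out fold, keeping predictors chosen
in a majority of folds — is reconstructed as a separate procedure.  The
stepwise criterion is the likelihood-ratio test (alpha_enter 0.05,
alpha_remove 0.10), the more stable convention at n = 60; the logistic
fits use IRLS with explicit detection of complete separation (a separated
candidate is unselectable in that step).  The candidate atlas the original
selection ran over is not published; the procedure therefore accepts any
candidate matrix and is validated on synthetic ground truth.

## Evaluation statistics

Accuracy, sensitivity and specificity are computed with responder as the
positive class; percentages are reported at full precision and rounded
half-away-from-zero to whole percent (66.67 -> 67).  Metrics with a zero
denominator are reported as undefined, not as 0 or 100.  Cohort
comparisons use Fisher's exact test (two-sided by the point-probability
rule) for binary covariates and the Mann-Whitney test for numeric ones
(exact null distribution for combined n <= 20 without ties, otherwise the
tie- and continuity-corrected normal approximation).  The "two-sample
binomial test" for comparing accuracies between validation studies is
implemented as a pooled-variance two-sided z-test, with continuity-
corrected and Fisher variants selectable, since the variant used
originally is not stated.  Non-inferiority power is estimated by Monte
Carlo for the one-sided exact binomial test of H0: p <= margin (the
rejection region is an upper tail, so a closed-form check accompanies
every estimate); the method behind the originally reported power value is
unstated, so no attempt is made to reproduce that number.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the classifier
assumes, so that every stage is testable without patient data:

* per channel, four independent unit-variance band-limited Gaussian noise
  carriers (frequency-domain synthesis), scaled by per-band RMS
  amplitudes (theta 6, alpha 10, beta 4, gamma 2 uV — typical adult scalp
  magnitudes);
* piecewise-constant condition modulation shared by everyone: alpha
  suppressed to 0.6 during both eyes-O/C blocks, theta x1.5 and beta x1.3
  during hyperventilation (classic alpha blocking and hyperventilation
  slowing; realistic patient magnitudes are not published, so these are
  order-of-magnitude defaults, all configurable);
* a class-dependent reactivity multiplier g on the feature cells — by
  default g = 1.5 for responders on four of the eight features, spanning
  both activation conditions and all four bands — which is the only thing
  separating the classes;
* a pink (1/f) background per channel, SD 10% of the total carrier RMS;
* rendering at an ideal common reference (1000 Hz by default), then a
  linear transform into either recording dialect.  Both dialects of one
  subject share identical sources, which is what makes the cross-system
  invariance property testable.

**Closed-form expectation.**  Envelope power follows squared carrier
amplitude, so a feature cell with modulation m and reactivity g has ideal
relative power (m g / m_rest)^2.  The pipeline, however, measures at the
Fz/Fp1/Fp2 average reference, and since carriers are independent across
channels the subtraction *adds* 1/r^2 of each reference member's in-band
power to every channel (and scales a member's own contribution by
(1-1/r)^2); the pink floor adds a further condition-independent in-band
offset.  `expected_feature_value` accounts for both terms by default and
matches pipeline measurements to within Monte-Carlo error; the ideal-
reference form is available via `reference=None`.

**Problem sizes.**  Cohort simulations default to the study sizes (35
responders / 25 non-responders).  Pure-cohort experiments render TruScan-
dialect subjects directly at 128 Hz: every generated carrier lies below
45 Hz, so the 128 Hz rendering is statistically identical to rendering at
1000 Hz and resampling, at an eighth of the cost.  Cross-dialect
comparisons always render shared 1000 Hz sources.

**What the generator does not emulate**: biophysical source geometry and
volume conduction (carriers are channel-independent, so real inter-channel
correlation structure is absent), epileptiform transients, artifacts
(blinks, muscle, electrode drift beyond 1/f), non-stationarity within
conditions, and between-subject variability in baseline amplitudes.
Passing tests therefore demonstrate that the pipeline and classifier are
correct under the model's assumptions — not that the published clinical
accuracy would replicate on new patients.

## Numerical details

* EDF I/O: 16-bit EDF+C with a symmetric digital range (+/-32767) so 0 uV
  is exactly representable; the physical range defaults to symmetric
  coverage of the signal extrema, bounding round-trip error by one
  quantization step.  Events travel as EDF+ annotations (TALs) and/or a
  TSV sidecar; the sidecar wins on conflict.
* Channel order is fixed to a canonical 19-label list; readers reorder and
  accept modern T7/T8/P7/P8 spellings.
* All internal signal values are microvolts; envelopes are uV^2.
* Segment means use all samples (no edge trimming) by default; a trim
  parameter exists.
* Determinism: every stochastic component is driven by an explicit seed;
  per-subject seeds derive from the master seed via a seed sequence and
  are recorded in cohort manifests.

## Known limitations

* The original raw patient EEG is not redistributable, so the published
  clinical headline numbers are reproduced from the published confusion
  outcome, not recomputed from signals.
* The published Mann-Whitney cohort p-values require unpublished raw
  covariates of the training cohort and are not asserted.
* The stepwise reconstruction cannot be checked against the original
  selection run (candidate atlas unpublished); it is validated on
  synthetic ground truth only.
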