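# Methods

`selanet` implements confidence-score-based selective detection of sleep
apnea from two easily wearable-accessible signals: ECG-derived respiration
(EDR) and oxygen saturation (SaO2).  This note documents the model, the
numerical choices, the synthetic study conditions, and what the bundled
experiments do and do not demonstrate.

## The selective prediction model

A selective classifier is a pair (f, g): a prediction function f and a
selection function g that scores how much f's answer should be trusted.
With confidence threshold τ,

    (f, g)(x) = f(x)          if g(x) ≥ τ
                "don't know"  otherwise.

Coverage φ(g) = E[g(x)] is the expected confidence, and the selective risk

    R(f, g) = E[ℓ(f(x), y) · g(x)] / φ(g)

is the loss restricted (softly) to accepted samples.  On a sample set
S_m = {(x_i, y_i)} these become the empirical coverage φ̂ (mean of g) and
empirical selective risk r̂ (g-weighted mean loss over φ̂).

Training minimises the risk subject to a *target coverage* c — the model
must keep accepting at least a fraction c of samples, so it cannot cheat by
rejecting everything difficult.  The constraint is enforced by an
interior-point (quadratic hinge) penalty:

    L_(f,g) = r̂(f, g | S_m) + λ · Ψ(c − φ̂(g | S_m)),    Ψ(a) = max(0, a)²

An auxiliary head h with plain cross-entropy L_h keeps the shared
representation discriminative while g is free to specialise in selection;
the final objective is the convex combination

    L = α · L_(f,g) + (1 − α) · L_h.

Defaults follow the reference operating point: λ = 200, α = 0.3, minibatch
64, Adam with lr 0.001 halved on plateau, 300 epochs at full scale.  φ̂ in
the training loss is computed per minibatch — the only tractable reading
under minibatch optimisation.  The per-sample loss ℓ inside r̂ is
cross-entropy, matching the auxiliary loss.  At inference τ defaults to c.

### Architecture

* **Feature extractor** — a temporal-convolutional-network (TCN)
  autoencoder.  The encoder runs one residual block per dilation rate
  (1, 2, 4, 8, 16; 10 filters; kernel 3; causal, so each output step sees
  only past samples) over the 30-s two-channel segment (2 × 6000 values),
  average-pools time by 8 then 5 (6000 → 150 steps) and projects with a
  kernel-1 convolution to 8 channels: a (150, 8) latent, 1,200 numbers for
  12,000 — fixed 10:1 compression.  The decoder mirrors it: nearest-
  neighbour ×40 up-sampling, TCN stack, kernel-1 projection to 2 channels.
  Trained on MSE with Adam.  The pooling mechanism for the ×40 reduction
  and the in-block kernel size are design choices (the factorisation 8 × 5
  gives mild per-stage reduction); any mechanism producing the (150, 8)
  latent is admissible.
* **Selective classifier** — a 1-D CNN-LSTM body over the latent (two
  causal conv blocks, 32 and 64 filters, kernel 5, ×2 average pooling each,
  then an LSTM with 64 units whose final hidden state feeds the heads):
  f = dense → 2-class softmax; g = dense → batch norm → sigmoid (scalar);
  h = dense → 2-class softmax.  Body widths are unconstrained design
  choices exposed in the estimator's parameters.

### Numerical choices

* **Selection-head initialisation.**  The batch-norm shift in g is
  initialised to logit(c) and its scale to 0.1, so the empirical coverage
  *starts* at ≈ c and the penalty only has to hold it there.  Started at
  the conventional 0.5, coverage must be dragged across half the sigmoid
  range through a single normalised shift parameter at Adam-step speed;
  at desk scale (tens of batches per epoch) it visibly stalls mid-range
  while λΨ and the risk term fight over the scale parameter.  Initialising
  at the operating point removes that transient without changing the
  objective or its optimum.
* **Plateau detection** uses the training objective (halve lr after 10
  epochs without improvement, floor 1e-5).  At desk scale the validation
  objective is dominated by coverage-penalty noise (λ = 200 amplifies
  ±0.02 fluctuations in val-set mean confidence into ±0.5 loss swings),
  which triggers spurious halvings.  Final weights are still selected by
  best validation objective.
* **Degenerate batches.**  g comes through a sigmoid so φ̂ > 0 strictly
  during training; the arithmetic-level `selective_loss` defines the
  φ̂ = 0 case as risk 0 plus the full penalty, which preserves the gradient
  direction that pushes g back up.
* **Ties** in f's probabilities break toward apnea (sensitivity first).
* **Metrics with zero denominators** are reported as NaN, never as 0.

### Evaluation statistics

Accuracy, sensitivity, specificity, FNR, FPR, F1 from the confusion counts
with apnea as the positive class; G-mean = √(sensitivity × specificity).
Coverage violation is the mean over evaluation units of |c − φ̂(unit)|.
The unit is a consecutive block of 64 test samples (the training batch
size).  A single whole-dataset unit cannot be what a violation of 0.114
next to |0.90 − 0.897| = 0.003 describes, so a per-batch dispersion
statistic is used; the grouping (blocks or per-subject) is switchable.
Empirical coverage is reported both soft (mean g) and hard (selected
fraction at τ); Table-style reporting uses the soft mean.

## Synthetic study conditions

The generator emulates the *physiology the detector exploits*, not ECG
morphology:

* **ECG**: a quasi-periodic train of QRS-like Ricker (second-derivative-of-
  Gaussian) deflections, half-width 20 ms, 1 mV, plus white noise
  (default sd 0.05 mV).  The RR interval carries baseline respiratory
  sinus arrhythmia (amplitude 0.2 × `hrv_depth`, 0.25 Hz) and one
  bradycardia–tachycardia cycle per apnea event with fractional depth
  `hrv_depth` = 0.25 — the cyclic heart-rate variation that makes EDR
  informative.  RERA-like events get half that modulation.
* **SaO2**: baseline 96.5 % with a delayed desaturation after every
  event — linear fall starting `desat_lag_s` = 10 s after event onset,
  full depth (4 % for the apnea family, one third for RERA) at event end +
  lag, exponential resaturation (τ = 10 s).  Overlapping dips combine by
  maximum, so recovery tails do not stack.  Noise has a white component
  (sd 0.15 %) plus a slow sinusoidal baseline wander at 3× that amplitude;
  both scale with `noise_sd_sao2`, so the noise-free generator is exactly
  reproducible analytically.  The wander mimics the slow drift of real
  pulse-oximetry traces; without it a normal segment would be flat white
  noise, which no encoder can reconstruct, and a reconstruction-quality
  bound would be unmeetable by construction rather than informative.
* **Events**: apnea events arrive by an exponential-gap renewal process
  (35/h, durations uniform 10–40 s — the apnea definition's ≥ 10 s
  minimum), which forbids overlap by construction while preserving the
  target rate; subtype labels follow large-PSG-corpus proportions
  (hypopnea 50 %, obstructive 28 %, central 20 %, mixed 2 %).  RERA events
  (10/h, 5–30 s) are thinned Poisson arrivals around them.  Records are
  3-h night slices at 200 Hz; every draw derives from one seed.

What this emulates: event-locked RR modulation, delayed desaturation,
an ambiguous intermediate class, subject-level variability (per-subject
seeds), detector-stressing noise.  What it does not: real QRS morphology,
arrhythmia, movement artifacts, sleep staging, inter-subject physiological
diversity beyond random event placement, or the label noise of human
scorers.  Passing the bundled experiments therefore shows the *method* is
implemented correctly and optimises what it claims to optimise — not that
the trained weights would transfer to clinical recordings.

## Preprocessing

R peaks: 5–20 Hz band-pass (4th-order Butterworth, zero-phase), squaring
(the nonlinear transform), Gaussian smoothing and a first-order Gaussian
differentiator (σ = 25 ms) whose falling zero crossings mark energy
maxima; candidates must exceed 0.3× the local (2-s rolling) energy maximum
— a true QRS dominates any 2-s neighbourhood, noise bumps do not — and a
250-ms refractory rule keeps the stronger of close pairs.  EDR: the RR
tachogram (each RR value at its later peak time) cubic-spline interpolated
onto the 200-Hz grid, held constant outside the first/last knot.  SaO2
repair: samples outside 50–100 % or arriving via a > 4 %/sample jump are
linearly interpolated from valid neighbours (thresholds are physiological
plausibility choices, configurable).  Channels are min–max normalised per
*recording* (not per segment), preserving inter-segment desaturation depth
— the discriminative signal.  Windows: 30 s with 5-s overlap between
consecutive windows (stride 25 s).  Labels: ≥ 10 s cumulative apnea-family
overlap → apnea; no event overlap → normal; ≥ 1 s RERA overlap → ambiguous
(excluded from the two-class stream, kept for test-time rejection
profiling); windows with 0–10 s apnea overlap are dropped as label noise.
Splits are by subject (70/5/25); train and test streams are balanced by
seeded undersampling of the majority class.

## Desk-scale problem sizes

The bundled acceptance experiment (`scripts/acceptance.py`) uses a
20-subject cohort (≈ 7,400 windows, ≈ 2,600 balanced training segments),
autoencoder training on a 256-segment subsample for up to 40 epochs
(batch 32, early stop patience 8), and selective training for 50 epochs
(batch 64) per target coverage c ∈ {0.90, 0.95, 0.98}.  The test-suite
fixture runs the same recipe at the same cohort size with a fixed seed.
These sizes are the
package's desk-scale defaults; the full-scale settings (300 epochs,
hundreds of subjects) are plain parameter changes.

## Known limitations

* The numpy training engine is single-threaded and desk-scale by design;
  it favours exactness and testability (finite-difference-verified
  gradients) over throughput.
* Class balance is assumed at training time; deployment under realistic
  imbalance needs ROC-threshold re-calibration (the G-mean criterion is
  implemented, the tuning study is out of scope).
* EDR here is the HRV-tachogram variant only; amplitude-based EDR and PPG
  surrogates are out of scope.
* WFDB input needs the optional `wfdb` dependency ecosystem; EDF input
  needs `mne` (optional extra).  The native container (npz + JSON sidecar)
  is the tested interchange format.
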