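# Methods

## Problem and pipeline

`gaitdx` classifies walking trials of children with spastic diplegia into
the four clinical gait forms (I–IV) used in top-down motor-organization
assessment, from the trajectories of 19 reflective markers sampled at
100 frames/s.  The pipeline is:

1. **Subsampling** — every second frame is kept (100 → 50 frames/s), with
   no interpolation or filtering, bringing the temporal resolution close to
   what a clinician perceives.
2. **Gait events and trimming** — foot strikes and toe-offs are detected
   from the heel (LCA/RCA) and toe (LFM/RFM) markers; the trial is trimmed
   to the span between its first and last strike so it covers a whole
   number of steps.  The average step period `T` is trimmed duration
   divided by step count, where a *step* is the interval between strikes
   of alternating feet.
3. **Angles** — markers are projected orthographically onto the three
   lab-fixed body planes (sagittal X–Z, frontal Y–Z, transverse X–Y; X is
   the direction of progression, Y the subject's left, Z up).  In each
   plane, 27 marker-triplet interior angles (vertex at the middle marker)
   are computed, giving 81 angles per frame.
4. **Spectral features** — for each angle, the DFT of the full trimmed
   series is sampled at bins 0, N, 2N, …, 19N, where N is the step count;
   with the trial trimmed to exactly N steps these are the harmonics of
   the single-step fundamental.  Complex magnitudes are kept; entries
   2–20 are normalized by the fundamental amplitude (bin N), the DC entry
   is kept raw.  Result: an 81 × 20 matrix per trial.
5. **Windows** — the angle series is also cut into 75-frame windows every
   15 frames, at most 45 per trial, for the sequence classifier.
6. **Datasets** — patients are split 0.75 : 0.25 into train/test per form;
   all trials of a patient stay on one side.  Form-1 training items are
   duplicated (×2) to soften class imbalance; test data are never
   augmented.
7. **Models** — an MLP on the flattened 1620-dim spectral vector (one
   prediction per trial), a single-layer LSTM on the windows (one
   prediction per window), and an RBF-SVM baseline on the spectral vector.
8. **Evaluation** — per patient, predicted forms are counted over all of
   that patient's trials (MLP/SVM) or windows (LSTM); top-k accuracy asks
   whether the true form is among the k most frequent.  Reports give
   per-form and patient-weighted overall top-1/top-2 plus a 4 × 4
   patient-count confusion matrix.

## Loss and training

The training criterion is the categorical cross entropy averaged over both
samples and classes,

    L = -(1/(N·M)) Σₙ Σₘ y_t[n,m] · ln y_p[n,m],    M = 4,

so the uniform predictor scores ln(4)/4 ≈ 0.3466.  Predicted
probabilities are clipped at 1e-12 inside the logarithm so a
confident-wrong prediction yields a large finite loss rather than an
overflow.  Both networks use Adam at its canonical defaults (lr 1e-3,
β₁ 0.9, β₂ 0.999, ε 1e-8), minibatches of 100 with reshuffling at each
epoch.  The MLP stops at the end of the first epoch whose mean training
loss is below 0.10, with a hard cap of 500 epochs; the LSTM trains for
exactly 15 epochs.  "Epoch" means a full pass over the training set.

Model specifics:

* **MLP** — dense ReLU stack, default hidden sizes (256, 128, 64, 32) in
  descending order with 256 units first, one dropout layer (rate 0.5, the
  standard value for dense layers) after the first hidden layer, softmax
  over the 4 forms.  An alternative layer-sizing rule is available for
  ablation sweeps: first hidden layer 32 units, each additional layer
  doubling the previous (32, 64, 128, …).  Empty `hidden_sizes` reduces
  the model to multinomial logistic regression.
* **LSTM** — exactly one recurrent layer (default 128 units, tanh cell
  with sigmoid gates, forget bias initialized to 1) consuming the 75 × 81
  windows; its final hidden state feeds a ReLU dense stack
  (128, 64, 32) and a softmax.  One prediction per window.
* **SVM** — one-vs-rest SVC with RBF kernel, C = 1, kernel width
  `gamma = 1/(n_features · var)` (scikit-learn's "scale"); both are
  configurable.

The neural layers, backpropagation (including truncated-free full BPTT
through the 75 steps) and Adam are implemented in numpy inside the
package (`gaitdx._nn`) and verified against finite-difference gradients in
the test suite; training is deterministic bit-for-bit under a fixed seed.
All features are standardized to zero mean and unit variance using
training-set statistics before entering any model — the raw DC spectral
entry is orders of magnitude larger than the normalized harmonics, and
none of the classifiers is scale-invariant.

## Event detection

The clinical workflow marks foot strikes visually; an automatic proxy is
needed for an executable pipeline.  Strikes are local minima of the
lightly smoothed (Savitzky–Golay, window 9, order 2) heel-marker height,
peak-picked with a minimum separation of 0.6 gait cycles (cycle length
estimated from the dominant frequency of the heel-height spectrum) and a
prominence of 0.3 × the height range, gated to frames whose forward heel
speed is in the lower three quartiles, restricted to minima within 15% of
the heel-height floor, and finally refined by the vertex of a local
parabola fit (±8% of a cycle) — the heel trajectory is nearly quadratic
around contact, so the fit cancels most of the marker noise.  The signal
is reflect-padded so strikes close to the trial boundaries are kept.
Toe-offs are the vertical-acceleration maxima of the toe marker within
the 75% of the cycle following each strike.  Hand annotations can be
injected instead via a CSV sidecar (`side,event,frame`).

## Synthetic cohort

Clinical gait recordings of this population are not publicly available,
so the package ships a parametric simulator used by all tests.  It is
phenomenological, not biomechanical: a pelvis advances one step length
per step with sinusoidal vertical (±12 mm) and lateral (±18 mm)
oscillation; each ankle follows a scripted trajectory (forward oscillation
of half a step length around the pelvis; height a raised-cosine lift of
90 mm per cycle, minimum at the scripted strike); knees are placed by
two-link inverse kinematics; the trunk tilts forward by the antepulsion
parameter and sways laterally at the stride rhythm; arms swing in
anti-phase with the ipsilateral leg.  Per-patient marker-placement
offsets (SD 4 mm, constant within a patient) emulate skin-marker
placement variability — and remove the exact bilateral symmetries an
idealized skeleton would have.  Form profiles follow the qualitative
clinical traits, each form maximizing its own distinguishing parameter:

| parameter           | I    | II   | III  | IV   | patient SD |
|---------------------|------|------|------|------|------------|
| trunk lean (°)      | 18   | 6    | 4    | 1    | 1.5        |
| stance knee flexion (°) | 8 | 25   | 8    | 5    | 2.0        |
| stride length (mm)  | 750  | 450  | 700  | 850  | 30         |
| frontal sway (°)    | 3    | 3    | 14   | 2    | 1.0        |
| equinus (°)         | 12   | 8    | 5    | 20   | 1.5        |
| step period (s)     | 1.1  | 0.9  | 1.0  | 1.0  | 0.03       |

Within-trial step periods jitter with SD 0.04 s; marker noise is
independent Gaussian, default SD 1 mm per coordinate (typical
optoelectronic accuracy).  The default cohort is 6/16/12/26 patients for
forms 1–4 (the uneven clinical prevalence at roughly one-third scale,
~60 patients), 3 trials of 8 s per patient — sized so the full pipeline
with both network trainings runs in minutes on one CPU.

What the simulator deliberately does **not** model: ground-reaction
forces, EMG, walking aids (the canes typical of form I have no marker
correlate in this marker set), pelvic rotation, foot-ground contact
mechanics, and the perceptual impairment characteristic of form III —
clinically, form III is identified partly through dysperceptive signs
that leave no kinematic trace, so real form-III gait is far more
confusable with its neighbours than the synthetic version, which is
separable through sway amplitude alone.  Passing the end-to-end tests
therefore shows that the pipeline machinery recovers class structure that
is present in the markers; it does not certify clinical accuracy on real
cohorts, where reported patient-level accuracies of comparable systems
are substantially lower for the intermediate forms.

## Numerical choices and edge cases

* Triplet angles use `arccos` of the clipped normalized dot product;
  projected marker pairs closer than 1e-9 mm raise a degenerate-geometry
  error identifying the frame and triplet.
* Spectral rows whose fundamental amplitude is below 1e-12 have their
  normalized entries zero-filled (with a logged warning) instead of
  failing the trial: one flat angle should not discard a walk.
* A trial needs at least 20·N frames for the 20 harmonics and at least
  75 frames for one window; shorter trials are excluded from the RNN
  dataset with a logged warning.
* The spectral window is the whole trimmed trial with no taper; trimming
  to whole steps is the leakage control.
* Patient-split rounding is to the nearest count with at least one train
  and one test patient per form; frequency ties in majority voting break
  toward the lower form index and set a `tie` flag so overlap cases can
  be audited.
* All randomness (cohort, split, weight init, batching, dropout) derives
  from one root seed through `numpy.random.SeedSequence` spawns.

## Open design points, resolved

* The lab axis convention and the plane definitions (lab-fixed, not
  pelvis-fixed) are declared conventions; the angle set is invariant to
  rigid translation and uniform scaling either way.
* The DC spectral entry is the raw DFT magnitude at bin 0 (not the mean
  angle).
* Top-2 accuracy ranks aggregated prediction frequencies, not averaged
  probabilities, mirroring the frequency-based top-1 definition.
* Window length (75), stride (15), window cap (45), harmonic count (20),
  subsample factor (2), split ratio (0.75), batch size (100), the 0.10
  stopping threshold, the 500-epoch MLP cap and the 15-epoch LSTM budget
  are fixed pipeline constants; the run configuration exposes cohort,
  model-width and seed choices.

## Known limitations

* The C3D codec covers Intel-ordered files with standard POINT
  parameters — enough for ingest of typical optoelectronic exports and
  for write-then-read round trips; it does not write analog channels or
  vendor extensions.
* Event detection assumes forward walking along a straight line with at
  least two gait cycles per side.
* The LSTM trains on CPU in float64; wall time grows linearly with the
  number of windows (~0.4 s per 100-window batch at 128 units).
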