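# gaitdx

Automatic classification of diplegic gait into the four clinical forms of
motor organization, from 3-D motion-capture marker trajectories.

Spastic diplegia — the sub-type of cerebral palsy in which the lower limbs
are more compromised than the upper — is clinically divided into four
walking patterns of increasing motor-repertoire richness: form I
(pronounced forward trunk lean, toe balancing), form II (crouch gait with
marked stance knee flexion and short steps), form III (frontal trunk
swinging with balancing upper limbs), and form IV (predominantly a motor
deficit, with marked equinus at walking onset).  Assigning a child to a
form guides prognosis and treatment, but the assignment is done by expert
observation.  `gaitdx` implements an end-to-end automatic pipeline that
does it from the 19-marker trajectories routinely recorded in motion
analysis labs, and a synthetic gait simulator that makes every stage
testable without clinical recordings.

## What it computes

From each walking trial (19 labelled markers at 100 frames/s, read from
C3D or a plain-text fixture format):

* **81 angles per frame** — markers are projected onto the sagittal,
  frontal and transverse body planes, and 27 marker-triplet interior
  angles are measured per plane (hip/knee/ankle chains, arm geometry,
  pelvis-trunk alignment, inter-limb relations).
* **Step-synchronized spectral features** — the trial is trimmed to a
  whole number N of steps, so the harmonics of the single-step fundamental
  sit at every N-th DFT bin; 20 harmonic amplitudes per angle (normalized
  to the fundamental, DC kept raw) give an 81 × 20 matrix per trial.
* **Sequence windows** — 75-frame windows every 15 frames (≤ 45 per
  trial) for the recurrent classifier.
* **Three classifiers** — an MLP on the flattened spectral vector, a
  single-layer LSTM on the windows, and an RBF-SVM baseline, trained with
  the categorical cross entropy

      L = −(1/(N·M)) Σₙ Σₘ y_t[n,m] · ln y_p[n,m]

  (M = 4 forms), Adam, minibatches of 100; the MLP stops when the epoch
  loss drops below 0.10 (cap 500 epochs), the LSTM after 15 epochs.
* **Patient-level scores** — each patient's form is the majority vote of
  their per-trial (MLP/SVM) or per-window (LSTM) predictions; reports give
  per-form and overall top-1/top-2 accuracy and a patient confusion
  matrix.

See `docs/methods.md` for the model details, the simulator design and its
deliberate limitations.

## Worked example

Simulate the default ~60-patient cohort, run the whole pipeline and
evaluate on the held-out patients:

```
$ gaitdx all --seed 1 -o runs/demo
lstm: patient top-1 0.733, top-2 1.000
mlp: patient top-1 0.867, top-2 0.933
svm: patient top-1 0.933, top-2 0.933
reports written to runs/demo
```

Each line is a classifier's patient-level accuracy on the 15 held-out
synthetic patients: top-1 is the fraction whose most frequently predicted
form is the true one, top-2 allows the second most frequent as well.
`runs/demo/` holds the per-form reports, e.g. `lstm_accuracy.csv`:

```
form,T1,T2
1,0.5000,1.0000
2,0.7500,1.0000
3,0.6667,1.0000
4,0.8333,1.0000
overall,0.7333,1.0000
```

plus the confusion matrices, training-loss traces, the split manifest and
an echo of the resolved configuration (`config.yaml`) so any number in the
run directory can be regenerated from it alone.  The library API mirrors
the stages (`gaitdx.synth`, `gaitdx.preprocess`, `gaitdx.features`,
`gaitdx.dataset`, `gaitdx.models`, `gaitdx.evaluate`); `gaitdx simulate`
writes cohorts as text fixtures and `gaitdx features` extracts spectral
features to CSV.

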