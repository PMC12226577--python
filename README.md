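# doorecg

Biometric personal identification from single-lead ECG measured through a
doorknob-style electrode system — the scenario where a door unlocks for a
registered household member simply because they grab the handle. Contact
through a doorknob and capacitive floor electrodes yields a far noisier
signal than clinical electrodes, so this package implements and evaluates
the two preprocessing ideas that make identification workable at that
signal quality:

1. **Synchronized averaging** of consecutive heartbeat segments, and
2. **Training-data augmentation** by mixing segments averaged over
   different numbers of beats.

It is aimed at biomedical-signal-processing researchers and students who
want a complete, reproducible ECG-biometrics pipeline with a controllable
synthetic data source: real doorknob-ECG corpora are not publicly
deposited, so the package ships a multi-subject simulator with known
ground truth.

## Method

The biometric feature is the **high-frequency ECG (HFECG)**: the
40–150 Hz band around the QRS complex, whose notch/slur fine structure is
stable within a person and differs between people. The pipeline is:

- **Filtering** (zero-phase IIR Butterworth cascades):
  Filter 1 = HP 0.5 Hz (order 4) → LP 150 Hz (order 12), the ECG band used
  for R-peak detection; Filter 2 = HP 40 Hz (order 4) → LP 150 Hz
  (order 12), the HFECG band.
- **Segmentation**: one 200-sample window per beat, 75 samples before the
  detected R peak and 125 after (0.2 s at 1,000 Hz).
- **Synchronized averaging**: the n-averaged segment is
  x̄ᵢ = (1/n) Σⱼ₌ᵢ..ᵢ₊ₙ₋₁ xⱼ over consecutive beats of one recording; the
  time-locked waveform is preserved while uncorrelated noise variance
  drops by 1/n (amplitude SNR gain √n), n ∈ {1,…,5}.
- **Datasets**: per subject, a beat-level 70/30 train/test split (averaged
  test segments never share a source beat with training segments), with
  named training compositions such as `2,3avg-140TD` = 70 twice-averaged +
  70 three-times-averaged segments per subject.
- **Classifiers**: a three-layer neural network (200 → 100 ReLU → K
  sigmoid units, binary cross-entropy, Adam lr 0.001, batch 16, 200
  epochs, seeded) and a linear soft-margin SVM (C = 1, one-vs-rest); the
  predicted subject is the argmax over the K registered identities
  (closed set).
- **Evaluation**: K×K confusion matrices with accuracy = trace/total;
  each condition is repeated over 10 cycles of re-randomized 70/30 splits
  and reported as mean ± SD.

## Worked example

Simulate a 10-subject door-electrode cohort (twelve 20-s records per
subject), extract segment pools, and evaluate the SVM at three averaging
counts:

```python
from doorecg import (
    simulate_cohort, SessionSpec, corpus_from_records,
    Condition, run_cycles,
)

records = simulate_cohort(10, sessions=[SessionSpec(n_records=12)], seed=1)
corpus = corpus_from_records(records)
for n in (1, 3, 5):
    res = run_cycles(corpus, Condition(classifier="svm", n_avg=n),
                     cycles=10, base_seed=1)
    print(f"SVM, {n}-beat averaging: {100*res.mean_accuracy:.1f}% "
          f"(SD {100*res.sd_accuracy:.2f})")
```

prints

```
SVM, 1-beat averaging: 82.3% (SD 1.88)
SVM, 3-beat averaging: 98.0% (SD 0.83)
SVM, 5-beat averaging: 99.6% (SD 0.59)
```

Single raw beats under doorknob-grade noise identify the subject ~82% of
the time; averaging five consecutive beats (≈5 s of contact at resting
heart rate) recovers near-perfect identification — the core usability/
security trade-off the system exposes.

The same pipeline is scriptable from the shell:

```
doorecg simulate --subjects 10 --records 12 --seed 1 --out cohort/
doorecg sweep --cohort cohort/ --kind averaging --epochs 40 --out results/
```

## Layout

- `doorecg.synth_ecg` — subject templates, noise models, cohort simulator, CSV/JSON cohort I/O
- `doorecg.preprocess` — Butterworth filter cascades, R-peak detection
- `doorecg.segment_average` — 200-sample beat windows, synchronized averaging
- `doorecg.dataset` — leakage-guarded splits, named training compositions
- `doorecg.classify` — seeded numpy NN, linear SVM, model serialization
- `doorecg.evaluate` — confusion/accuracy, cycle runners, experiment sweeps
- `doorecg.cli` — `doorecg` command-line interface
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
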