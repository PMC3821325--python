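# neospike

Two-stage detection of epileptiform spikes in single-channel EEG.

Interictal spikes — pointed transients of 20–70 ms — and spike-and-slow-wave
complexes are the EEG hallmarks used to diagnose epilepsy, and finding them
by eye in hours of recording is slow and subjective. `neospike` implements a
classic two-stage detector for neurophysiologists and methods researchers
who want a transparent, fully testable reference implementation:

1. **Candidate detection.** Each 10-s trial x(n) is z-normalized and passed
   through the k-point nonlinear energy operator

   Ψ_k{x(n)} = x²(n) − x(n−k)·x(n+k),

   which is large only where the signal is simultaneously high-amplitude
   and high-frequency. Ψ_k is smoothed with a unit-sum Hamming window of
   length 4k+1 and thresholded at T; every supra-threshold run containing
   an upward peak of the normalized signal yields one candidate. For
   20–70 ms spikes at 256 Hz the matching half-widths are 2.56–8.96
   samples, so k = 3 by default and T = 1.8.

2. **Candidate classification.** Around each candidate peak P the model
   locates the flanking minima A and B (spike onset/offset) and, on a 5 Hz
   zero-phase low-pass of the trial, the slow-wave peak Q and end R. From
   the five landmarks it computes 13 morphological features (durations,
   amplitudes, slopes, chord-excess areas) in three nested sets — FS1 (6
   conventional spike features), FS2 (+3 slow-wave features), FS3 (+4
   composite spike features) — and classifies each candidate as
   *single_spike*, *spike_slow_wave* or *non_spike* with AdaBoost.M1:
   100 rounds of depth-1 decision trees, round weights log(1/β_t) with
   β_t = ε_t/(1−ε_t).

Evaluation follows a 4-fold stratified cross-validation repeated 10 times
(accuracy, sensitivity, specificity; three-class and merged
"pseudo-two-class" scoring). A synthetic EEG generator with ground-truth
annotations — amplitude-stable theta rhythm over a 1/f floor, plus injected
spikes and half-sine slow waves — makes every stage testable without any
clinical data.

## Worked example

```python
import neospike as ns

cfg = ns.SimConfig(seed=0)                      # 42/100/111 trials, 10 s @ 256 Hz
trials, annotations, _ = ns.gen_dataset(cfg)

run = ns.RunConfig()                            # k=3, T=1.8, 5 Hz, 100 rounds, 4x10 CV
print(f"recovery: {ns.recovery_rate(trials, annotations, run, tol=3):.1f}%")

table = ns.build_feature_table(trials, annotations, run)
print(table["label"].value_counts().to_string())

model = ns.AdaBoostM1.from_dataframe(
    table, feature_cols=ns.FEATURE_SETS["FS2"], rounds=100, seed=0
)
print(model.fit().summary())

report = ns.cross_validate(
    table[list(ns.FEATURE_SETS["FS2"])].to_numpy(float),
    table["label"].to_numpy(),
    mode="three", feature_set="FS2", seed=0,
)
print(report.summary())
```

prints

```
recovery: 100.0%
label
non_spike          145
spike_slow_wave    100
single_spike        42
AdaBoost.M1 results
===================
examples            287
features            9
classes             non_spike, single_spike, spike_slow_wave
weak-tree depth     1
rounds requested    100
rounds used         100
beta range          [0.1909, 0.9623]
training accuracy   94.4%
Repeated cross-validation report (three-class mode, FS2)
========================================================
examples 287, 4-fold x 10 repeats (40 model fits)
accuracy_train          96.9 +/- 0.5 %
accuracy_test           93.0 +/- 1.0 %
```

Every injected spike is recovered by the energy-operator stage
(`recovery: 100.0%`); the detector also fires on ~0.5 background
fluctuations per trial, which become the non-spike class the classifier
learns to reject. The cross-validated three-class accuracy with FS2 (93.0%)
exceeds FS1's (84.1% on this dataset) because only the slow-wave features
separate single spikes from spike-and-slow-wave complexes.

The same pipeline is available from the shell:

```sh
neospike simulate --out-dir data/ --seed 0
neospike detect   --input data/single_spike_000.csv --fs 256 --out cands.tsv
neospike extract  --data-dir data/ --out features.tsv
neospike train    --features features.tsv --featureset FS2 --out model.json
neospike evaluate --features features.tsv --featureset FS2 --mode three --out report.json
```

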