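# Methods

## Detection stage

A trial is one channel of EEG over a fixed review window (default 10 s at
256 Hz, the standard per-page review length). Each trial is z-normalized
with its own mean and *population* standard deviation (divide by N; the
trial is the entire population of interest, and at N = 2560 the
sample/population distinction is immaterial). Normalization makes
detection invariant to positive affine rescaling of the raw signal, so
amplifier gain and offset are irrelevant; a constant trial cannot be
normalized and is rejected as degenerate.

The k-point nonlinear energy operator Ψ_k{x(n)} = x²(n) − x(n−k)·x(n+k)
responds to transients that are simultaneously large and sharp; its lag k
matches peaks of half-width ≈ k samples. Spikes of 20–70 ms at 256 Hz have
half-widths of 2.56–8.96 samples (duration × fs / 2), so the useful
integer resolutions are k = 3…8 and the default is k = 3, the sharp end of
the range. Positions where Ψ_k is undefined (the first and last k samples)
are set to 0 so edges can never cross a positive threshold.

Ψ_k is smoothed by convolution with a Hamming window of length 4k+1
normalized to unit sum. Unit-sum normalization keeps the energy scale —
and therefore the meaning of the threshold T = 1.8 — independent of k.

Thresholding alone would flag every sample of a spike, so candidates are
consolidated: each maximal run of supra-threshold samples contributes at
most one candidate: among the strict upward peaks of the normalized
signal inside the run (x(n−1) < x(n) ≥ x(n+1), plateau ties to the
earliest index), the one with the largest *unsmoothed* Ψ_k value at the
peak itself. Pointwise Ψ_k is the natural ranking: it quantifies exactly
the "large and pointed" property that defines a spike apex, and because
it is evaluated at the peak it cannot be displaced. The two plausible
alternatives both fail in corner cases: the smoothed-energy maximum lags
the apex by the window width (selecting a small wiggle beside the spike),
and the raw amplitude maximum can sit on the crest of the following slow
wave when a low spike rides a background trough. Runs without an upward
peak (e.g.
purely negative-going transients) are discarded. No refractory distance
beyond run consolidation is imposed.

## The five-landmark spike model

Around a candidate peak P the spike limbs are traced outward to the
nearest flanking local minima: A on the left (spike onset) and B on the
right (offset). A flat neighbour counts as a turning point; if a limb
reaches the trial edge without turning, the candidate is reported as
unbounded. "Tracing until the slope turns" is read as *stopping at the
flanking minimum*: immediately beside a peak every slope points up toward
it, so the turning point is the first sample where the signal stops
descending away from P.

The slow wave is measured on a separate copy of the trial filtered with a
zero-phase (forward–backward) 4th-order Butterworth low-pass at 5 Hz —
zero phase so landmark timing is not shifted, 5 Hz as the upper edge of
the slow-wave band. On this copy, Q is the highest point after B and R
the lowest point after Q, both within a search window of 1 s after B
(slow waves are sub-second events; an unbounded search would drift to
unrelated activity). The last window sample is excluded from the Q search
so R always has room after Q; windows truncated by the trial end are used
as-is and the candidate is flagged as truncated. Q is searched after B,
not after P, because the slow-wave portion begins at the spike offset.

Thirteen features in four families are computed from the landmarks,
durations in samples, amplitudes in normalized units:

| family    | features |
|-----------|----------|
| duration  | Dur_AP = P−A, Dur_PB = B−P, Dur_spike = Dur_AP+Dur_PB, Dur_slowwave = R−B |
| amplitude | Amp_AP = x(P)−x(A), Amp_PB = x(P)−x(B), Amp_spike = (Amp_AP+Amp_PB)/2, Amp_slowwave = ((x̃(Q)−x̃(B)) + (x̃(Q)−x̃(R)))/2 |
| slope     | Slope_AP = Amp_AP/Dur_AP, Slope_PB = −Amp_PB/Dur_PB, Slope_sharpness = Slope_AP−Slope_PB |
| area      | Area_spike, Area_slowwave |

Spike features are read from the normalized signal x, slow-wave features
from the filtered signal x̃ on which Q and R were located, keeping each
measurement consistent with its localization. Areas are *chord-excess*
areas: the trapezoidal integral of the waveform from A to B (or B to R)
minus the trapezoid under the chord joining the endpoints. This makes the
area features baseline-independent and exactly zero for flat or linear
segments.

The nested feature sets are FS1 (the six conventional spike features),
FS2 (FS1 + the three slow-wave features) and FS3 (FS2 + the four composite
spike features), in a fixed documented order.

## Classification

AdaBoost.M1 over depth-limited CART trees (scikit-learn
`DecisionTreeClassifier`; depth 1 — stumps — by default, the canonical M1
weak learner). Each round fits a tree on the weighted sample, computes the
weighted error ε_t, keeps the round if ε_t < 1/2 with confidence
β_t = ε_t/(1−ε_t), multiplies the weights of correctly classified
examples by β_t and renormalizes. Prediction is the label with the largest
Σ log(1/β_t) vote, ties broken by label-set order.

Numerical choices: ε_t is clamped to [1e−10, 0.5−1e−10] before forming
β_t; a round with raw ε_t = 0 is kept and training stops (the weight
update would degenerate); a round with ε_t ≥ 1/2 is discarded and
training stops, except at round 1 where the single tree is retained with
clamped confidence so a degenerate sample still yields a usable model.
Trees are scale-invariant so no feature standardization is applied. The
seed only breaks ties between equally good splits; training is otherwise
deterministic. For two classes the procedure coincides with scikit-learn's
SAMME AdaBoost, which serves as an independent cross-check in the test
suite (never as the implementation).

Models serialize to JSON (label set, per-round tree structure, betas) and
reload as predict-only ensembles.

## Evaluation protocol

Stratified k-fold cross-validation (default 4 folds) repeated (default 10
times) with a fresh shuffle per repeat. Stratification is used because
with ~42 examples in the smallest class, unstratified 4-fold splits risk
folds nearly empty of that class. Within a repeat, each fold serves once
as the test set; the *pooled* test predictions over the k folds give the
repeat's test metrics, and the repeat's training accuracy is the mean of
the k training-set accuracies. Reported values are mean ± sample SD
(ddof = 1) over repeats, in percent.

Two-class mode reports accuracy, sensitivity (TP/(TP+FN)) and specificity
(TN/(TN+FP)); three-class mode reports accuracy (trace/total).
Pseudo-two-class mode trains the three-class classifier but scores the
confusion matrices after merging the two spike classes into one positive
class; merging turns spike-vs-spike-with-slow-wave confusions into correct
classifications, so merged accuracy can never be below three-class
accuracy. Per-repeat shuffle seeds derive from (seed, repeat) via
`numpy.random.SeedSequence`, so reports are exactly reproducible.

## Synthetic data

The generator produces the study conditions the pipeline is evaluated
under: 42 single-spike, 100 spike-with-slow-wave and 111 background-only
("normal") trials of 10 s at 256 Hz — the class proportions of a typical
clinical candidate pool.

**Background.** An amplitude-stable cosine rhythm (default 6.5 Hz, theta —
typical of drowsy adult EEG) whose phase performs a slow random walk
(0.06 rad/sample, giving a realistic sub-Hz linewidth), mixed with a
band-limited (1–70 Hz) 1/f broadband floor carrying 20 % of the variance.
Two properties motivated this split over plain 1/f Gaussian noise, whose
single tilt parameter cannot deliver both:

* the smoothed k-NEO of pure background must cross T = 1.8 occasionally
  (≈ 0.5 events per 10-s trial), supplying the non-spike candidates the
  classifier learns to reject — with an amplitude-stable rhythm these
  crossings come only from the floor, whose share sets the rate;
* the sub-5 Hz background component must stay small (≈ 0.3 SD) so that
  injected slow waves of 1–3 SD are actually separable in the slow band;
  Gaussian 1/f noise red enough to keep the crossing rate low puts most
  of its power below 5 Hz and buries the slow wave.

The rhythm sits where the k = 3 operator's gain sin²(kω) is small, and a
constant-envelope oscillation has no amplitude excursions, so it
contributes essentially no crossings — matching the clinical observation
that detectors fire rarely on healthy background. Out-of-band power is
< 1 % of the total.

**Events.** Spikes are asymmetric triangles (rise 40 % of the duration,
so the two half-wave slopes differ generically) of 20–70 ms and 5–8
background SDs, placed ≥ 1 s from trial edges. The amplitude floor is set
by construction of the evaluation: the shortest (20 ms) spike riding a
trough of the background rhythm must still push the smoothed k-NEO above
T = 1.8, and below 5 SD such worst-case events sit exactly on that
boundary — the synthetic study emulates confidently identified
epileptiform events, not threshold-straddling ones. slow waves are half-sine
bumps of 150–500 ms and 1–3 background SDs appended at the spike's last
sample, so the spike offset B is shared between spike and slow wave. One
event is injected per spike-class trial by default, making the event
counts equal the trial counts (configurable up to two). Every level of
the generator is deterministic under its seed; per-trial seeds are
spawned from the dataset seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about clinical data: alpha spindles, eye-blink and muscle
artifacts, electrode pops, multi-channel correlation, non-stationary
state changes, polyspikes, sharp waves (70–200 ms), and the amplitude
statistics of real epileptiform discharges, which the generator's declared
SNR constants do not estimate. Synthetic results demonstrate the
pipeline's mechanics and the discriminative value of the slow-wave
features under the stated conditions, not clinical performance.

## Problem sizes

The default synthetic study (253 trials × 2560 samples; ≈ 280–290
candidates; 4-fold × 10-repeat CV at 100 boosting rounds per feature set)
was sized so the complete acceptance run finishes in about a minute on a
single CPU; unit tests use reduced datasets (≈ 30–55 trials) with the
same generator defaults.

## Known limitations

* Single-channel only; no montage logic or cross-channel evidence fusion.
* The detector has no adaptive threshold; T = 1.8 presumes z-normalized
  trials and the unit-sum smoothing window.
* Slow-wave localization inherits the low-pass filter's undershoot: R
  settles on the filter's trailing trough, up to a few tens of
  milliseconds after the visual end of the wave.
* AdaBoost.M1 stops when no weak learner beats 1/2 weighted error; with
  stumps on hard three-class problems this can end training early.
  Deeper weak trees are available via `max_depth`.
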