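# Methods

## Problem and model

The package classifies a subject's attention level — high, medium or low —
from simultaneously recorded physiological channels. The discriminative
signal is assumed to live primarily in the relative EEG band powers
(β vs. α and θ, the classical engagement indices), with complementary
information in ocular activity (blink/saccade statistics reach the EOG
spectra), cardiac dynamics (heart rate and its variability) and the
auxiliary SpO2/HR scalars.

Classification operates on per-frame feature instances: a channels ×
(bins + ratios) log-power map (15 × 93 by default) plus two time-domain
scalars, 1397 features in total. The classifier (MEAN) is a deliberately
small network:

1. **Channel attention** — squeeze s_c = (mean_c + max_c)/2 over each
   sensor row, excitation FC(15→5)–ReLU–FC(5→15)–sigmoid, multiplicative
   gate per sensor. Reduction ratio 3 is the smallest that still gives a
   genuine bottleneck at 15 channels.
2. **Spatial attention** — the map is treated as one image plane; the
   stacked plane average/max statistics pass through a 7×7 convolution
   (padding 3) and a sigmoid to give a position-wise gate. We read the
   attention as a true 2-D gate over the channel–frequency plane; the
   alternative reading (sensors as image channels, gating frequency only)
   is a known ambiguity of this architecture family.
3. **Mapping blocks** (×4) — star operation: element-wise product of a
   linear 1-D convolution branch (kernel 3, padding 1, single channel) and
   a ReLU6 convolution branch, combined with the input through two
   learnable scalar residual weights initialized at 0.5. Algebraically one
   star operation of an augmented d-vector spans (d+2)(d+1)/2 pairwise
   monomials — an implicit polynomial feature expansion, verified against
   symbolic expansion in the tests.
4. **Head** — conv(1→8, k7, s2)–ReLU–maxpool2 → conv(8→16, k5, s2)–ReLU →
   global average → FC(16→64)–ReLU–dropout(0.3) → FC(64→3) → softmax.
   The identical head consuming the raw flattened vector is the CNN
   baseline, so the CNN comparison doubles as an ablation of the attention
   and mapping stages.

Features are z-scored per feature with statistics from the training fold
only. Training: Adam, lr 1e-3, weight decay 1e-4 (L2 folded into the
gradient), batch 64, cross-entropy; fully deterministic given the seed.
The whole model has ~2.3k parameters (a hard ceiling of 10k is asserted as
the lightweight-design contract).

Because no deep-learning framework is part of this package's dependency
set, the networks run on a small reverse-mode autodiff engine over NumPy
arrays (`meanbci.nn`), with convolution/pooling gradients verified against
finite differences and the forward operators against `scipy.signal`
correlation in the test suite.

## Preprocessing decisions

* **Resampling** is Fourier-domain (spectral truncation), so anti-aliasing
  is implicit; everything is brought to a common 200 Hz grid. The SpO2
  channel is recorded at 80 Hz and *upsampled* to the grid — the
  synchronization direction is ambiguous in descriptions of such rigs; we
  document upsampling as our choice.
* **Filtering**: 50 Hz notch (configurable to 60 Hz mains), then 2–50 Hz
  band-pass; windowed-sinc Hamming FIR with ~1 Hz transition width
  (order ≈ 3.3·fs/transition), applied forward–backward for zero phase.
* **Segmentation** trims each marked state interval symmetrically to the
  target duration, discarding transition periods at both boundaries
  equally.
* **ECG baseline wander** is removed morphologically (below); EEG/EOG rely
  on the 2 Hz high-pass edge instead.
* **Heart rate** uses adaptive-threshold peak picking on the 5–30 Hz
  band-passed ECG (threshold 0.4× the 99th percentile, 0.33 s refractory
  distance), 60/mean(RR) per 5 s window, carry-forward for windows with
  fewer than two peaks.

## Morphological baseline estimation

Erosion and dilation are defined on their valid index ranges
(min/max of f(n±m) ∓ k(m)); after each primitive the result is
edge-replicated back to the input length so opening/closing and the
two-stage averaged estimator compose cleanly. Consequences: values within
one element length of the edges are approximate, and the decomposition
identity (corrected + baseline = input) holds to floating tolerance
everywhere. The structuring element is flat (all zeros) with default
length 0.25 s × fs (50 samples at 200 Hz): longer than a QRS complex
(~0.1 s), much shorter than wander periods (>1 s). The same element is
used at both averaging stages. Element length and shape are exposed in
configuration; the defaults are design choices, not reconstructions of any
particular recording rig.

## Spectral features

* 9 s Blackman window, 1 s hop → raw bin spacing 1/9 Hz, ≈88.9 % overlap.
* Frequency compression sums **linear** power in groups of three raw bins
  (then re-applies the log): summing power, not log-power, is the
  physically meaningful aggregation. The DC bin is excluded, so the 90
  retained bins have centers in (0, 30) Hz; after the 2 Hz high-pass the
  lowest bins carry little power.
* Temporal smoothing is a centered 3-frame moving average with edge
  truncation — the smallest symmetric kernel.
* Band ratios are computed from linear band power with an ε = 1e-12 guard
  in logs and denominators, for **all** 15 channels (uniform feature
  structure across modalities), using θ 4–8, α 8–13, β 13–30 Hz.
* Scalars are aligned to frames by the mean over each frame's 9 s window.

## Synthetic data: what it emulates and what it does not

Each recording has three consecutive 600 s states (default) at native
rates. Per state profile:

| state  | θ : α : β amplitude | blink/min | HR (bpm) |
|--------|---------------------|-----------|----------|
| high   | 0.5 : 0.7 : 1.2     | 8         | 76 ± 2.5 |
| medium | 0.8 : 1.0 : 0.9     | 14        | 70 ± 2.5 |
| low    | 1.2 : 1.4 : 0.6     | 22        | 62 ± 2.5 |

so β/(α+θ) is strictly ordered 1.0 > 0.5 > 0.23 — the direction, not the
magnitude, is the claim. Informative EEG channels carry band-limited
oscillations (unit-RMS spectral-masked noise per band, 10 µV per amplitude
unit) over a 1/f background of 10 µV RMS; by default the last three EEG
channels are noise-only controls used by the channel-attention attribution
check. ECG is a Gaussian-bump P-QRS-T template at jittered RR intervals
with a sinusoid-plus-slow-noise wander (0.3 mV, 0.25 Hz) returned
separately as ground truth. EOG electrodes share common-mode backgrounds
and differ by blink bumps / saccade steps; pulse waves are locked 0.25 s
after each R peak; SpO2 is a bounded slow walk around 97 %.

Not emulated: realistic ECG morphology variants, electrode pops/EMG
artifacts, volume conduction and channel correlation structure,
cross-subject variability, non-stationarity within a state. Passing the
end-to-end checks therefore demonstrates that the pipeline recovers the
class structure it was designed to exploit — not that the reported
accuracy transfers to human recordings.

## Evaluation protocol

Within each class, instances are time-ordered and split into five
contiguous blocks (the first n mod 5 blocks one element longer); fold j
tests on block j of every class and trains on the rest, so train and test
are never temporally interleaved. Each fold × repetition cycle draws a
fixed proportion (default 0.8) of both train and test without replacement.
The repetition count is a parameter (default 5 → 25 cycles); descriptions
of this protocol family disagree between 25 and 50 cycles, so we expose it
rather than hard-code it. Per-class metrics come from the aggregated
predictions; the reported σ is the sample standard deviation of fold-mean
accuracies. Zero-denominator metrics return 0 with a warning so degenerate
folds do not abort sweeps. Report tables round half-up to 4 decimals
(metrics) and 2 decimals (accuracy %).

Sequence baselines (RNN/LSTM, 2 × 128 hidden units) consume the 15×93 map
as a 15-step sequence of 93-vectors with the scalars appended to the final
hidden state — the layout is our choice; all models receive the same fused
representation. The SVM baseline is a linear-kernel SVM
(scikit-learn `LinearSVC`) on the standardized flattened vector.

## Problem sizes used by the tests and acceptance script

The synthetic end-to-end runs use 120 s per state (336 instances) and
5-fold temporal CV with one repetition per fold, over 3 seeds (accuracy)
and 5 seeds (channel-weight ranking). 120 s keeps the full pipeline —
synthesis at 1000 Hz through CV training of the NumPy network — at a size
a single CPU handles comfortably. At this size a CV training fold has only
~215 instances, five times fewer optimizer steps per epoch than a
full-length 600 s session, and the 30-epoch/lr 1e-3/batch 64 defaults
demonstrably undertrain (sigmoid-gate warmup leaves some cycles on a loss
plateau); the scaled protocol therefore trains each cycle for 45 epochs at
lr 3e-3 with batch 32, which reaches convergence (final loss ≲ 0.03) on
these problem sizes. Oracle suites use 200 random signals (N ≤ 200,
M ≤ 20) for morphology and d ≤ 6 for the star-operation expansion.

## Known limitations

* The synthetic class structure is linearly separable by construction, so
  the linear-SVM baseline saturates near 100 % on generated data and the
  relative ordering of classifiers seen on real multimodal recordings
  (where the attention network is the strongest model) does not emerge
  here. The synthetic end-to-end checks validate the pipeline's
  correctness, not architectural superiority.

* Edge samples of morphological outputs are approximate (replication
  padding); irrelevant at 0.25 s elements on 2-minute segments.
* The spatial-attention stacked statistics are degenerate for a
  single-plane input (average = max = the plane); the gate remains a
  learned 7×7 local function of the plane.
* The NumPy training loop is single-threaded; it is sized for the
  documented problem sizes, not for GPU-scale experiments.
* The HDF5/NPZ container stores one subject per file; multi-subject
  studies loop over files.
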