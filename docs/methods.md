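# Methods

`eegdenoise` removes physiological artifacts (blinks, eye movements,
chewing, teeth clenching, and related motion) from multichannel EEG by
training a recurrent generator adversarially against a recurrent
discriminator, using a classical wavelet-threshold cleaner to produce
the clean reference targets. This note documents the models, the
defaults and why they were chosen, the synthetic data the package tests
itself on, and the known limits of both.

## Pipeline

1. **Band-pass** 0.5–40 Hz, 4th-order Butterworth applied
   forward–backward (zero phase, so spike latencies are not displaced).
   The band keeps the classical EEG rhythms and rejects 50/60 Hz line
   noise and slow electrode drift.
2. **Min–max normalization** per channel onto [−1, 1]:
   `x ↦ 2(x − min)/(max − min) − 1`. Per-channel scope is the weakest
   assumption that bounds every downstream window; the (min, max) pairs
   are retained so the map is invertible. A constant channel maps to
   zeros and is flagged.
3. **Epoch clipping.** Each task annotation is clipped with its 2-s
   relax flanks: an 11-s task yields a 15-s epoch of
   `F = T × fs` frames (1920 at 128 Hz). Consecutive epochs may share
   the 2-s relax between them. An epoch whose flank crosses a recording
   boundary is truncated and flagged (or skipped under `strict`).
4. **Segmentation** into non-overlapping 5-s windows (640 samples at
   128 Hz), per channel; a trailing remainder is dropped. A 15-s epoch
   over 32 channels yields 96 segments.
5. **Subject-held-out split**: all segments of one subject form the
   test set, the rest train (80:20 with 5 subjects).

## Wavelet reference cleaner

Targets `S` are produced from artifacted segments by
(a) subtracting a Savitzky–Golay trend and (b) multilevel DWT
thresholding: decompose to level 5 (db4, symmetric extension), set

    t = 0.8 × std(d3)

from the third detail band, threshold **all** detail bands at `t`,
keep the approximation untouched, reconstruct.

Parameter choices that were genuinely open, and how they were settled:

* **Hard thresholding** (default). Soft shrinkage subtracts `t` from
  every surviving coefficient; with `t = 0.8σ(d3)` that removes most of
  the power of genuine oscillations — a pure 10 Hz test tone keeps only
  ~8% of its alpha power. Hard thresholding keeps above-threshold
  coefficients intact (the same tone keeps ~100%), which is what a
  *reference* signal must do. Soft mode remains a switch.
* **Trend window 33 samples (~0.26 s), order 3.** The trend step is
  the cleaner's only mechanism that can absorb smooth sub-4-Hz ocular
  transients: blink lobes live mostly in the approximation band, which
  the thresholding never touches. A ~1-s window leaves blink peaks
  essentially intact (ratio ≈ 1.0); the quarter-second window rides
  through the lobe and cuts peaks by ~60% on the seeded fixtures while
  passing oscillations above ~5 Hz. The cost is partial attenuation of
  the 4–6 Hz lower theta range — visible in the theta row of the band
  tables, and consistent with the general pattern that the cleaner's
  gains grow with frequency.
* The single threshold from d3 is applied to every detail level; no
  per-level thresholds.

## Adversarial denoiser

The generator maps one normalized 5-s window `(640, 1)` to a cleaned
window of the same shape: four LSTM layers of 64 units returning full
sequences, each followed by a PReLU (learnable per-feature slope,
init 0.25), then a per-timestep dense 64 → 1 with tanh, confining the
output to (−1, 1). The discriminator stacks LSTM layers of
1024/512/256/128 units with LeakyReLU (slope 0.2) between, flattens
(640 × 128 = 81,920 wide) and scores real-vs-generated through one
sigmoid unit.

Training alternates per batch:

* **Discriminator step** — binary cross-entropy on wavelet-cleaned
  references labeled 1 and generator outputs labeled 0 (one combined
  batch; labels are not smoothed).
* **Generator step** (discriminator frozen) — minimize
  `1.0 × MSE(S′, S) + 5e−4 × BCE(D(S′), 1)`. The adversarial gradient
  flows *through* the discriminator to the generator; the
  discriminator's own accumulated gradients are discarded, so its
  weights are bit-identical across a generator step (asserted by
  checksum in the tests).

Both networks use Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8). The full-scale
`paper` preset trains with learning rate 1e−3, batch 128, 500 epochs.
The discriminator is unconditional — it sees a single segment, not a
(noisy, candidate) pair. Ground-truth clean signals from the simulator
are **never** used in training, only the wavelet targets; simulator
ground truth serves evaluation.

All layers, backpropagation and Adam are implemented in numpy inside
`eegdenoise.nn` (gate order i/f/g/o, Glorot input weights, orthogonal
recurrent weights, forget bias 1). Single-threaded numpy makes training
bit-reproducible for a fixed seed on one platform; gradients are
verified against central finite differences in the test suite.

### Desk preset

Training the full Table-scale pair on one CPU core is a multi-day job,
so the package ships a `desk` preset used by the tests and the
acceptance script: generator 2 × 16-unit LSTM layers, discriminator
(32, 16), 2 simulated subjects × 8 channels × the four evaluated
artifact kinds (88 train / 88 test segments), 30 epochs, batch 8,
learning rate 3e−3. The small batch matters: with ~90 segments, batch
128 would give a single update per epoch and the generator would still
be near its mean-predicting initialization after 30 epochs; batch 8
gives 11 updates per epoch, and the reduced model tolerates the higher
learning rate. The objective, update cadence, and pipeline wiring are
identical to the full preset. A desk run takes roughly three minutes
and reaches test RMSE against the wavelet reference of ~0.08 versus
~0.17 for the raw input, with band SNR gains in all four bands.

## Evaluation metrics

For original `org` and reconstruction `rec` (length N):

* `MSE = ‖org − rec‖² / N`, `NMSE = MSE / ‖org‖²` (an option switches
  the denominator to `N·var(org)`), `RMSE = √MSE`.
* `CC` — Pearson correlation.
* `SNR_band = 10 log₁₀(P_in / P_out)` where `P_in` sums squared DFT
  magnitudes over bins with `lo ≤ |f| < hi` (rectangular window, no
  averaging) and `P_out` is the remaining spectrum. The DC bin is
  excluded from both pools; the half-open band convention means a
  disjoint band cover exactly tiles the AC spectrum (Parseval-checked).
  Bands: Theta 4–8, Alpha 8–13, Beta 13–30, Gamma 30–50 Hz.
* `SAR = 10 log₁₀(σ(A) / σ(A − A′))` — standard deviations, not
  variances.

Degenerate cases (empty noise pool, perfect cleaning) are capped at
±300 dB and flagged rather than returned as infinities, so tables stay
machine-comparable. NMSE/RMSE/CC/SAR are computed per segment and
averaged within electrode; the report prints one row per electrode plus
an arithmetic `Mean` row, and one band-SNR row per band for
raw/wavelet/model.

## Synthetic sessions

The simulator emulates a consumer-wearable acquisition: 32 channels
(10–20 names, frontal first) at 128 Hz, nine (2-s relax, 11-s task)
pairs = 117 s = 14,976 samples per subject. The background is

* a power-law noise component (PSD ∝ 1/f, slope recoverable by
  periodogram regression when the other components are off),
* an equal-RMS white component standing for the broadband sensor/EMG
  floor that dominates consumer recordings during motor tasks,
* a 10 Hz alpha oscillation at half the noise RMS,

scaled to 20 µV RMS and zero-meaned per channel. Artifacts are injected
additively with a frontal-weighted spatial profile (gains 1.0 → 0.3
across the channel list), so the ground-truth decomposition
`contaminated = clean + component` holds exactly:

| kind | morphology | default RMS scale |
|---|---|---|
| eye blink | positive biexponential lobes, 0.4 s wide (rise τ = w/3, decay τ = 2w/3), 0.5–1 Hz | 6 |
| eye movement | smoothed 0.5 Hz square wave | 4 |
| chewing | 4–8 Hz carrier, amplitude-modulated at 1.5 Hz | 2 |
| clench teeth | 20–45 Hz noise bursts | 3 |
| other motion kinds | 10–30 Hz noise bursts | 2 |

Scales are multiples of the per-channel background RMS and follow
field-typical scalp amplitudes (frontal blink deflections several times
the background; EMG bursts a few times). No published values exist for
these amplitudes; they are simulator parameters, chosen once.

What the simulator does **not** model: volume conduction and realistic
spatial mixing, dipolar ocular forward fields, non-stationary
background rhythms, electrode pops, line noise (the band-pass would
remove it anyway), and the paper's note that subjects blinked during
non-blink tasks (a secondary-contamination switch exists in the API but
is off by default). Passing tests therefore show the pipeline's
machinery and the method's directional behavior — they do not certify
performance on real recordings.

## Numerical notes and limitations

* Determinism: every stage derives its seed from the master seed via
  `SeedSequence` with a CRC-stable stage tag; two runs with the same
  master seed produce byte-identical metric CSVs and manifests.
* EDF round trips are exact to the 16-bit quantization of the
  per-channel physical range (set from the data min/max); CSV round
  trips are exact. Segment containers store float32.
* The band-SNR absolute level depends strongly on the spectral shape of
  the data; across disjoint bands, at most one band can show a positive
  SNR under this definition, so only *differences* between methods are
  meaningful, not levels.
* The desk preset's problem sizes (2 subjects, 8 channels, 30 epochs)
  are the package's default small-machine configuration; the `paper`
  preset restores the full-scale architecture and training schedule.
* Iterating the wavelet cleaner is contractive on the test fixtures but
  not idempotent; it is applied once.
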