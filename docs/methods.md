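# Methods

`sonomoment` implements a per-subject pipeline that regresses the ankle's
net plantarflexion moment during walking directly from ultrafast B-mode
ultrasound of the plantarflexors (and, as a comparison modality, from
surface-EMG scalogram images). This note documents the models, the
numerical choices, and what the synthetic test bed does and does not show.

## Imaging front end

Raw data are plane-wave RF acquisitions from a 38 mm linear array (6.4 MHz
center frequency, 128 elements, 50 mm imaging depth, one zero-angle
transmit per frame at 1,000 FPS). Beamforming is plain delay-and-sum: for a
pixel at lateral x, depth z, the transmit delay is z/c and the receive
delay to element e is ||p − e||/c, with c = 1540 m/s (standard soft-tissue
value). Sub-sample delays are linearly interpolated (nearest-neighbour is
available); delays beyond the recorded samples contribute zero; no
apodization or compounding is applied. The vectorized implementation is
held equal (max |diff| < 1e−9 of peak) to a brute-force per-pixel delay
loop kept in the package as the plain statement of the sum.

Envelope detection uses the magnitude of the axial analytic signal, and log
compression maps an envelope ratio r to clamp(1 + 20·log10(r)/DR, 0, 1)
with DR = 60 dB by default — both the ubiquitous B-mode conventions; an
all-zero field maps to an all-zero image.

The reconstruction grid is isotropic 0.1 mm/px (500 rows × 380 columns for
50 mm × 38 mm), the smallest grid that contains a 300 × 300 px region of
interest centred at 0 mm lateral / 20 mm depth. Column n_cols//2 sits at
lateral 0 and row r at depth r·pitch; millimetre coordinates snap to the
nearest pixel with half-sample ties broken toward the smaller index
(documented and tested: 20 mm → row 200, so the 100 px ROI spans rows
150–249 and columns 140–239). ROI cropping is pure windowing — no
resampling.

## Gait segmentation

Heel-strike and toe-off are threshold crossings of the vertical GRF at 5%
of body weight; "5% body mass" is converted to newtons as 0.05·m·g with
g = 9.81 m/s², since force plates measure force. Windows are half-open
[heel-strike, toe-off) on the shared 1 kHz clock. Runs shorter than 0.2 s
are discarded as chatter (a debounce of our choosing; the emulated protocol
does not state one). Stance traces are resampled to percent-of-stance
(0% heel-strike, 100% toe-off) by linear interpolation onto 101 points, the
biomechanics convention.

## sEMG spectrum images

sEMG (1 kHz; LGS, MGS, SOL) is band-passed 20–450 Hz with a 4th-order
Butterworth applied forward–backward (zero phase; the order is our choice).
A 100-sample window sliding by 1 sample is transformed with a continuous
wavelet transform at integer scales 1–50, giving a 50 × 100 magnitude
matrix per channel per instant; the LGS and SOL matrices are stacked
vertically into a 100 × 100 image synchronized 1:1 with the ultrasound
frame clock. The wavelet is the analytic Morlet (`cmor1.5-1.0`), whose
scale-1 pseudo-frequency equals the sampling rate, so scales 1–50 span
1,000–20 Hz — covering the sEMG band exactly; the mother wavelet and scale
spacing are config options since the emulated protocol does not fix them.
Min–max normalization extrema are fitted on the training split only and
frozen for validation/prediction, so no label-side information leaks.

## The CNN regressor

The network has 31 layers: an image input, seven sets of convolution →
batch normalization → ReLU with filter counts 8, 16, 32, 32, 32, 32, 32, a
2 × 2 stride-2 average pooling after sets 1–6 (none after set 7), 20%
dropout, one fully connected unit, and a regression output. Convolutions
are 3 × 3, stride 1, 'same'-padded, so pooling alone halves the spatial
size: 100 → 50 → 25 → 12 → 6 → 3 → 1 (FC sees 32 features), 200 → … → 3
(288), 300 → … → 4 (512). The kernel and pooling sizes are exposed in the
spec object; 3 × 3 and 2 × 2 are the standard choices consistent with
size-preserving convolutions and per-set halving. The minimum input side is
64 px (anything smaller collapses before the sixth pooling; `build_cnn`
names the degenerate layer).

No neural-network framework is used: convolutions (im2col onto BLAS
matmuls), batch normalization, pooling, dropout, the backward passes and
the SGD-with-momentum optimizer are implemented directly on NumPy in
float32. The backward pass is verified against numerical differentiation
during development and the whole fit is a pure function of the seed
(He-uniform initialization, per-epoch shuffling and dropout masks all
descend from one seed), so identical seeds give bit-identical weights.

Training: mean-squared-error loss (any positive scaling of the quadratic
loss has the same optimum), mini-batches of 128, up to 30 epochs, learning
rate 0.001 dropping to 0.0001 after epoch 20, momentum 0.9 (the optimizer's
conventional default), validation every floor(n_train/batch) iterations.
Images are streamed from their source one mini-batch at a time — the
training set is never materialized — and are zero-centred by the
training-set mean image, the only input-normalization statistic, frozen
into the model for validation and prediction.

Cross-validation is leave-one-speed-out over the five treadmill speeds
(0.50–1.50 m/s) with eight stance cycles per speed: the first five cycles
of each speed form the fitting pool and the last three the prediction pool.
Each fold trains on the fitting cycles of the four non-held-out speeds
(20 cycles), validates on the fitting cycles of the held-out speed
(5 cycles; the 4:1 train/validation design), and predicts the remaining
15 cycles — 62.5% of cycles for fitting, 37.5% for prediction.

## Evaluation metrics and statistics

For paired truth/prediction series: quadratic loss (mean squared residual),
RMSE, N-RMSE (RMSE divided by the subject's peak ground-truth moment over
the prediction cycles), and R². R² defaults to the squared Pearson
correlation — both series' means enter the formula — with the residual form
1 − SS_res/SS_tot available behind a flag; the two coincide when the
prediction-vs-truth fit is near the identity line, which is the regime the
pipeline targets, so nothing downstream depends on the choice. Agreement is
additionally summarized by OLS of prediction on truth (slope, intercept,
their standard errors and t-test p-values) with the 45° line as reference.

Group comparisons gate on per-condition Shapiro–Wilk normality at α = .05:
all-normal takes the parametric track (repeated-measures ANOVA followed by
Tukey HSD, or a paired t-test for two conditions), otherwise Friedman
followed by a Tukey-style studentized-range comparison of mean ranks, or a
Wilcoxon signed-rank test. All tests are two-sided with significance flags
at .05/.01/.001.

## The synthetic generator

No recordings accompany the protocol this pipeline reproduces, so the
test bed is synthetic, with every random draw derived from one root seed
split into named substreams (schedule, moment, sEMG, image texture), making
any modality independently regenerable.

* **Moment**: peak·sin²(π·u^a) over stance fraction u, with a chosen so the
  single maximum falls at 75% of stance (push-off); zero at heel-strike and
  toe-off. peak = 60 + 40·speed Nm (≈80–120 Nm across 0.50–1.50 m/s,
  realistic for a 70 kg adult), perturbed per cycle by a 3% multiplicative
  factor. Cycle-to-cycle variability is a config parameter, not an asserted
  value.
* **Stance duration**: linear, 0.80 s at 0.50 m/s to 0.55 s at 1.50 m/s
  (frame counts per stance therefore decrease with speed), with 2% seeded
  jitter.
* **GRF**: a double-peaked bump (loading and push-off peaks, mid-stance
  valley) scaled to 1.1 × body weight, identically zero outside stance,
  with shoulders steep enough that the 5% body-weight crossing sits within
  ~1 sample of the scheduled edge — so segmentation accuracy is measurable
  to ±2 samples.
* **sEMG**: per channel, 20–450 Hz band-limited unit-RMS noise modulated by
  baseline + (1 − baseline)·m̂ where m̂ is the normalized moment advanced by
  the 50 ms electromechanical lead (inside the physiological 30–150 ms
  range); per-channel gains in (0.6, 1.0].
* **Image texture**: a per-cycle frozen speckle background (exponentiated
  smoothed Gaussian field) mixed with an oriented sinusoidal grating whose
  inclination (8° → 22°), spacing (12 → 8 px) and contrast (0.35 → 0.60)
  are each monotone affine functions of the instantaneous moment normalized
  by the dataset peak — the simplest texture realizing the premise that
  joint moment is encoded instantaneously and monotonically in the 2-D
  muscle image. An RF mode emits point-scatterer channel data instead, for
  beamformer integration tests.

What the generator does **not** emulate: acoustic wave propagation, muscle
mechanics (no Hill-type model), out-of-plane motion, probe pressure drift,
electrode noise artifacts, or inter-subject anatomical variability. Passing
tests therefore demonstrate that the pipeline's stages are individually
correct and that the trained network can invert a clean monotone
moment→texture encoding across speeds — not that the real-data accuracies
of the emulated study transfer.

## Problem sizes used in the shipped runs

The checked-in end-to-end run uses the full 5-speed × 8-cycle protocol on a
150 Hz frame/analog clock (trigger synchronization and all sample-alignment
invariants are unchanged), giving ≈2,000 training frames of 100 × 100 px
per fold, trained for 5 epochs. Under those conditions the held-out-speed
prediction reaches N-RMSE ≈ 3% and Pearson r ≈ 0.997 (seed 1), comfortably
inside the N-RMSE < 0.12 / r > 0.92 acceptance region and consistent with
the regime the full-scale protocol reports on real data. Unit tests use
smaller 64 px / 40–100 Hz configurations.

## Known limitations

* Single zero-angle plane wave only; no compounding, adaptive beamforming
  or scan conversion.
* The CNN trainer is CPU-bound NumPy: fine at desk scale, not intended for
  the full 1,000 FPS protocol.
* The Friedman post hoc uses the large-sample studentized-range
  approximation of mean-rank differences; exact small-sample tables are not
  implemented.
* `compare_groups` supports the paired/repeated-measures design only, which
  is the only design the protocol calls for.
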