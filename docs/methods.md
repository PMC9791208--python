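# Methods

This note documents the models and procedures implemented in `rfqus`, the
numerical choices behind them, and what the synthetic phantom does and
does not emulate.

## Data model and units

Raw RF data are 3-D arrays indexed `[axial, beam, frame]`: axial rows are
fast time, beams are lateral columns, frames are slow time. ROIs are
0-based and half-open. Physical conversions use the pulse-echo (two-way)
convention: the axial distance per sample is `c / (2 fs)`, with the sound
speed `c` carried in cm/s (clinical convention, default 154,000 cm/s =
1,540 m/s) and `fs` the sampling rate in Hz. At the clinical defaults
(32 MHz, 1,540 m/s) one millimetre spans 42 axial samples.

The on-disk format is a flat little-endian float32 binary in
axial-fastest order plus a `key=value` text sidecar. This is a
deliberately open layout; vendor RF containers are proprietary and should
be converted into it.

## Spectral features (37 per case)

The 0–25 MHz analysis range is partitioned into seven sub-bands,
`[0,1.5], [1.5,6.5], [6.5,10.5], [10.5,14.5], [14.5,18.5], [18.5,22.5],
[22.5,25]` MHz, placing a 4 MHz probe's fundamental and harmonics at
sub-band centers. Intervals are half-open `[f_l, f_u)` so band power is
additive over the partition.

The PSD is estimated from non-overlapping 1 mm × 1 mm patches anchored at
the ROI origin (partial edge patches dropped): per patch, each beam
segment is mean-removed, Hamming-windowed, zero-padded to the next power
of two ≥ twice its length and FFT'd; the patch PSD is the beam average of
`|FFT|² / (Σw² · N)`. Patch PSDs are aggregated by the arithmetic mean
(one value per case is required and the reducer is a config key).

Per sub-band, five statistics of the averaged PSD:

* signal power `Σ P(f) Δf`
* spectral centroid `Σ f P(f) Δf / Σ P(f) Δf`
* spectral bandwidth `sqrt(Σ (f − SC)² P(f) Δf / Σ P(f) Δf)` — reported
  as the square root of the weighted squared deviation so its unit is Hz,
  consistent with quoting centroid and bandwidth on one MHz scale
* spectral flatness: geometric / arithmetic mean of P(f) in band (1 for a
  flat spectrum, → 0 for tonal content; any zero bin makes it 0)
* crest factor: max / mean of P(f) in band (≥ 1, = 1 iff constant)

Bands that extend above the data's Nyquist frequency yield zeros plus a
warning rather than an error, so the 37-length contract holds on any
sampling rate (a 32 MHz acquisition can only populate the first four
bands).

The two regression features S1 (intercept) and S2 (slope) come from an
OLS line fitted to the max-normalized FFT magnitude spectrum of each RF
time series against frequency normalized to [0, 1]. Series are the
slow-time (frame-to-frame) sequences at each ROI pixel when at least 4
frames exist, otherwise the axial beam columns of the first frame;
per-series values are averaged. Two deliberate numerical choices:
zero-padding to the next power of two ≥ 2N (the padding length was
otherwise unspecified), and exclusion of the DC bin from the fit — after
mean removal that bin is identically zero by construction and would
otherwise tilt every fitted slope upward by a constant amount
(≈ +0.04 for white noise) regardless of the data.

## Parametric feature maps

All three maps use population (divide-by-n) moments and a crop edge
policy: only fully interior windows produce values, and each map records
the sub-ROI its values occupy instead of padding, so map statistics are
never contaminated by synthetic border values.

**Nakagami map (NDM).** The envelope (magnitude of the per-beam analytic
signal) is summarized by the moment estimate
`m = (E[R²])² / E[(R² − E[R²])²]` in a sliding window, step 1. `m < 1`
indicates pre-Rayleigh (sparse scatterers), `m = 1` Rayleigh speckle,
`m > 1` post-Rayleigh. The default window is ~3 pulse lengths axially ×
3 beams (derived from center frequency and sound speed via
`MapConfig.for_meta`), the established stability/resolution compromise.
Smaller windows overestimate m; with speckle-correlated samples the
effective sample count is the window size divided by the axial
correlation length, so map means run above the underlying m for small
windows (measured: ≈ +21% at 144×3, +4% at 301×9 on Rayleigh speckle).
Map variance decreases monotonically with window area.

**Direct energy attenuation map (DEA).** At sample i of a beam, the
direct energy coefficient compares a 64-sample segment starting at i
with a 64-sample segment starting at i+16:
`DEC = 10 log10(E0/E1) / d`, where `d = 16 · c / (2 fs)` cm is the
two-way depth increment (0.0385 cm at the clinical defaults), giving
dB/cm. Segment energy is the Parseval sum of squared FFT magnitudes of
the unwindowed segment, which reduces to the time-domain sum of squares;
the ratio cancels any fixed window. DEC operates on raw RF samples (the
source text does not say RF or envelope; RF was chosen and the choice is
a config surface). The map's valid region drops the trailing
`64 + 16 = 80` samples of each beam. For tissue attenuating at
α dB/(cm·MHz), the expected DEC level is ≈ 2·α·f₀ dB/cm (two-way travel).

**RF skewness map (RF-I).** Sliding-window third standardized moment of
raw RF samples (window defaults to the Nakagami window). Raw RF is
near-symmetric, so the map isolates amplitude asymmetry such as the
compression/rarefaction distortion of nonlinear propagation. Windows
with zero variance yield NaN (they cannot occur on noisy data).

## Radiomics (350 per map, 1,050 per case)

Per feature map: 16 histogram features, 23 GLCM, 13 GLRLM, 13 GLSZM and
5 NGTDM features on the original map, plus the same 70 on each sub-image
of a one-level 2-D DWT (Daubechies-4, symmetric padding; LL/LH/HL/HH),
i.e. 280 wavelet features. Conventions: 32 equal-width gray levels per
(sub-)image, re-quantized per sub-image; GLCM at distance 1 over four
directions, symmetric, direction-averaged, normalized; GLRLM descriptors
averaged over the four directions; GLSZM zones 8-connected; NGTDM with
edge-aware 8-neighborhood means; entropies in bits.

Two inventory slots are deliberate duplicates preserved for the
feature-count contract: the histogram block repeats kurtosis, mean,
variance and skewness on z-scored intensities (z-scoring is affine, so
the repeated mean/variance are the constants 0/1 and kurtosis/skewness
equal their raw versions), and the GLCM block carries the maximal
correlation coefficient twice. Downstream L1 selection discards constant
and duplicated columns, and the cross-validation scaler treats
zero-variance columns safely.

Degenerate inputs: a constant (sub-)image maps to a single gray level;
correlation-type GLCM features (correlation, IMC1/2, MCC) are then set to
0 with a warning; NGTDM coarseness is capped at 10⁶ when its denominator
vanishes.

## Synthetic phantom

Each beam is a 1-D scattering simulation: Poisson scatterer sites on the
sample grid, gamma-amplitude (mean 1) random-sign reflectivity, convolved
with a Gaussian-modulated cosine pulse (4 MHz, fractional bandwidth 0.6).
The default sampling rate is 64 MHz so the whole 0–25 MHz analysis range
is observable. There is no lateral point-spread function — no downstream
feature depends on lateral resolution shape — and no diffraction,
beamforming or elevation focusing.

`scatterer_density` is the mean number of scatterers per axial
resolution cell, with the cell defined as the intensity-effective pulse
length `(Σe²)²/Σe⁴` of the pulse envelope (~25 samples at defaults).
This definition makes the density dial act directly on the envelope
statistics: for N_eff effective scatterers,
`1/m ≈ 1 + (E[a⁴]/E[a²]²)/N_eff`, so densities ≥ ~16/cell give fully
developed Rayleigh speckle (m ≈ 1) while densities ≤ 1/cell are strongly
pre-Rayleigh. The gamma `amplitude_shape` (default 50, i.e. nearly
constant amplitudes) is the second dial: heavier-tailed amplitudes
(small shape) push the envelope further pre-Rayleigh at fixed density.

Attenuation (α, dB/(cm·MHz)) is applied in two parts: depth-banded
spectral tilt `10^(−α (f−f₀) 2d/20)` (unit gain at f₀, so the spectrum
downshifts with depth) and a smooth per-sample amplitude decay
`10^(−α f₀ 2d/20)` carrying the center-frequency energy loss. The DEA
map responds with mean ≈ 2·α·f₀ dB/cm.

Amplitude asymmetry is injected as the quadratic waveform distortion
`x → x + a (x² − E[x²]) / rms(x)`, emulating finite-amplitude
(nonlinear) propagation; the sign of `a` sets the sign of the RF
skewness. Sign-asymmetric reflectivity alone cannot produce measurable
RF skewness: convolution with a zero-mean band-pass pulse suppresses the
third moment of an asymmetric impulse train by the pulse's spectral
factor at the carrier (~10⁻³ here), which we verified numerically before
adopting the distortion mechanism.

Frames share scatterer positions; each later frame re-draws a fraction
`frame_jitter` of amplitudes (slow-time decorrelation over a multi-second
capture). White Gaussian noise is added at `noise_db` SNR (default
30 dB). Everything is deterministic given the `PhantomSpec` seed; cohorts derive
per-case seeds from a master seed via `SeedSequence`.

What the phantom does **not** emulate: anatomically realistic geometry,
lateral/elevational beam physics, tissue-dependent spectral scattering
laws, motion, or vendor pre-processing. Passing tests therefore
demonstrate correctness of the estimators and the absence of pipeline
leakage — not clinical-grade performance.

## Classification protocol

The per-case vector is 37 spectral + 3 × 350 map features = 1,087
columns. Selection is L1-penalized logistic regression over an inverse
penalty grid C ∈ logspace(−2, 1, 10), chosen by cross-validated
log-loss; features are z-scored inside the selector. Exact duplicates
receive a split of the weight one copy would get (L1 solutions are
non-unique along duplicated columns — the pair's combined coefficient is
the invariant quantity).

Evaluation is repeated stratified k-fold CV (default 50 × 10-fold; the
fold count drops to the minority class size when necessary).
Standardization and LASSO are re-fit inside every training fold by
default ("nested"), so held-out labels can never influence the trained
model; a "pre" mode (single selection before CV) exists for comparison
but is leakage-prone. The classifier is an RBF SVM with C = 1 and the
inverse-median-heuristic gamma computed on the training fold, with Platt
probability calibration; random forest (100 trees) and 5-NN run under
identical fold assignments for paired comparison. Per repeat, held-out
probabilities are pooled across folds; AUC comes from an
ascending-threshold sweep whose trapezoid area equals the Mann–Whitney
concordance probability (ties counted half), and accuracy/sensitivity/
specificity are taken at threshold 0.5. Results report mean and standard
deviation over repeats.

Group comparisons use Welch's two-sided t-test per feature (Student's
form behind a flag); features with zero variance in both groups are
flagged undefined.

A note on null calibration: cross-validated AUC on a no-signal cohort of
40 cases is itself a noisy quantity (≈ 0.09 ranking noise) with a known
mild pessimistic ("anti-learning") bias below 0.5; calibration checks in
the test suite therefore average over several independent null cohorts,
and the null generator holds generative parameters fixed across cases —
a cohort whose cases draw parameters from a common distribution with
nonzero spread contains real, learnable group differences at finite n
and is not a null.

## Problem sizes used in the test suite

Unit tests run on 512–2,048-sample phantoms. The end-to-end
discrimination checks use cohorts of 20+20 cases (768 × 48 × 4 stacks,
384 × 32 ROIs) under 10 × 10-fold CV, and estimator-recovery checks use
10⁵–10⁶ draws; these sizes give the estimators' asymptotics room while
keeping the whole suite in a few minutes on one CPU.
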