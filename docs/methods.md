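# Methods

This note documents the models, numerical choices and known limitations
of `msmorph`, in the order the processing pipeline applies them.

## Modulation spectrum

The modulation spectrum E(f_a, f_m) of an analysis frame is computed by
subband envelope detection. The acoustic axis [0, rate/2] is divided
into `n_acoustic_bands` (default 128) uniform bands. Each band's
analysis filter is a brick-wall bandpass centered on the band center
but widened to `2·max_mod_freq` (at least one band spacing): a
modulator at f_m places side bands at ±f_m around a carrier, so a
filter narrower than 2·max_mod_freq would truncate the very side bands
the modulation axis is supposed to measure. Filters therefore overlap;
the disjoint uniform partition is still used to decide which band
"contains" a given frequency (e.g. the pitch band in LMR). The masked
one-sided spectrum is inverted to an analytic subband signal whose
magnitude is the Hilbert envelope; coherent detection instead shifts
the subband to baseband by its center carrier and keeps the complex
low-pass signal. The envelope stays at full rate and is Fourier
analyzed over the whole frame, so modulation bins sit at multiples of
1/duration Hz; the 0 Hz (DC) bin is retained because LMR, PALA and RALA
are defined against it. A frame is warned about when its modulation
resolution is coarser than `max_mod_freq/4`.

Phase is unwrapped deterministically and separably: 1-D unwrapping
along the modulation axis of every acoustic band, then along the
acoustic axis. Cells whose modulus falls below `1e-12·max|E|` carry
numerical noise instead of phase and are zeroed first. This is a
documented simplification relative to quality-guided 2-D/3-D
unwrapping; for the smooth phase fields produced by sustained vowels
the separable scheme is adequate and exactly reproducible.

Band reduction partitions [0, max_mod_freq] into `nb` equal-width bands
and sums modulus energy |E|² per band; energy is conserved exactly and
`nb` is configurable in the conventional 4–26 range (the feature-vector
widths 20 and 44 quoted for the 6–18 band range extend to 52 at nb=22;
the implementation exposes nb freely).

## Morphological parameters

* **MSC** uses the band-reduced modulus energy as the mass in the
  centroid — a centroid of complex or signed mass is ill-defined.
  Zero-energy bands yield centroid 0 and a log message.
* **DRB** floors band energies at `1e-12·max` before `10·log10`.
* **LMR** takes the acoustic band containing the frame's pitch estimate
  and compares the first modulation band's energy with the cumulative
  energy up to and including the band containing 25 Hz — the range
  conventionally covering vocal tremor. It is ≤ 0 by construction.
* **MSW** sums `|M − M'| / (M + M')` over the four vertical/horizontal
  neighbors of each point and averages over points. The absolute value
  in the numerator is required: the signed Weber terms cancel pairwise
  over the full grid, so a signed sum cannot measure contrast. Pairs
  whose denominator magnitude is zero contribute 0.
* **MSH** is the mean squared deviation from the 3×3 local mean with
  truncated borders; the normalization is the point count. Any fixed
  normalization preserves the ranking of voices.
* **Texture image.** The modulus input to MSW/MSH is the dB modulus
  limited to a 40 dB dynamic range below the frame maximum (shifted so
  the floor is 0) — the way a modulation spectrogram is rendered. On
  the raw linear modulus both measures are dominated by numerically
  tiny floor cells whose relative fluctuations carry no voice
  information, and contrast then *decreases* with severity, the
  opposite of the perceptual expectation. 40 dB is a standard display
  range; the choice makes both modulus texture parameters invariant to
  global amplitude scaling. Phase variants use the unwrapped phase
  matrix directly.
* **CIL** converts the floored modulus to dB (20·log10), evaluates
  ascending/descending cumulative counts on a 1 dB grid anchored at the
  minimum level and interpolates the crossing linearly (midpoint of the
  flat region when the curves coincide over a range). For a symmetric
  level distribution CIL approaches the median level.
* **PALA/RALA** count points at or above (ties count as above) the
  linear modulus mean; RALA = PALA/(1−PALA) holds identically. A flat
  spectrum (no point below the mean) is rejected as degenerate.

Per-frame scale behavior, tested: MSC, DRB, LMR, MSW, MSH (texture
image) and PALA/RALA are invariant under `x → k·x`; CIL shifts by
exactly `20·log10(k)` dB.

## Preprocessing and the MFCC baseline

Frames are Hamming-tapered with 50% overlap; tail samples not filling a
frame are dropped. Pitch is estimated per frame by normalized
autocorrelation with parabolic peak interpolation over 60–500 Hz;
frames whose peak falls below 0.3, or whose RMS sits more than 40 dB
below the file RMS, are dropped from feature extraction — the
pitch-normalized parameters are undefined without a pitch. MFCCs use
30 triangular filters on the mel scale (near-linear below 1 kHz,
logarithmic above), log energies, an orthonormal DCT-II with the
gain-carrying 0th coefficient dropped, and per-file cepstral mean
subtraction. No pre-emphasis is applied. Δ is the standard FIR
regression filter of length 9 (half-width 4) and ΔΔ applies a length-3
filter to Δ, with edge replication.

## Dimensionality reduction, GMMs, decisions

Every cross-validation fold refits the whole back end on its training
files only. Features are first z-scored with training-fold statistics:
the raw features mix units whose variances differ by orders of
magnitude, and unstandardized PCA selects scale rather than structure
(on the synthetic corpus this costs ~25 points of efficiency). The PCA
percentage is interpreted as the fraction of *dimensions* removed
(`k = max(1, round(d·(1−pct/100)))`), signs fixed by making each
component's largest entry positive; LDA solves the generalized
eigenproblem `S_b v = λ (S_w + ridge I) v` with
`ridge = 1e-6·trace(S_w)/d` and keeps `#classes − 1` directions.

Each severity level gets a diagonal-covariance GMM fitted by EM from a
seeded k-means initialization, stopping when the mean log-likelihood
gains less than 1e-5 or after 200 iterations, with covariances floored
at `1e-6` of the feature variance. Diagonal covariances are a
deliberate bias: with 4–48 components and corpora of under a hundred
files, full covariances cannot be supported. A file's score under a
model is its mean per-frame log-likelihood, making scores invariant to
file length. For each unordered class pair the log-likelihood-ratio
threshold Γ is fixed at the equal-error-rate point of the training
*frame*-level LR distributions — a training fold holds too few files
per class for a stable EER estimate, while frames provide ~50× more
samples; at test time the per-file mean LR is compared against Γ (class
i wins at LR ≥ Γ, so exact ties prefer the lower severity). The
predicted level is the one with most pairwise wins; ties break on the
total score margin, then on the lowest level.

Validation is leave-one-out by default (a shuffled k-fold mode exists
for prospecting). Fold confusion matrices are summed; efficiency is
`100·trace/total` with a normal-approximation 95% binomial half-width
`1.96·√(p(1−p)/n)` — the formula reproduces the reference tables'
printed half-widths exactly (e.g. p = 0.816, n = 87 → 8.1). Cohen's κ
is computed from the summed matrix and interpreted on the Altman scale
after rounding to two decimals (≤0.20 Poor, 0.21–0.40 Fair, 0.41–0.60
Medium, 0.61–0.80 Good, 0.81–1.00 Excellent).

## Synthetic corpus

The generator renders sustained /ah:/-like phonations as 20 harmonics
with 12 dB/octave rolloff. Perturbations: sinusoidal pitch tremor
(extent in % of f0, rate 2–15 Hz) with optional amplitude tremor;
Gaussian cycle-to-cycle period jitter and cycle-amplitude shimmer
(std in %); white noise scaled to an exact harmonics-to-noise ratio
(generated signals verify within 1 dB against their noiseless twins).
Waveforms are pure functions of their `VoiceSpec` including its seed.
The default 4-level schedule spans clinically plausible ranges — class
0 at jitter ≤ 0.3%, tremor ≤ 0.5%, HNR ≥ 30 dB up to class 3 at jitter
2–4%, tremor 4–8% at 4–10 Hz, HNR 5–12 dB, with intermediate classes
interpolating — but is generator configuration, not a clinically
calibrated severity model: no perceptual validation is claimed, and no
formant/vowel-quality or running-speech modeling is attempted. What
passing tests show is that the features respond monotonically to this
perturbation structure and that the pipeline can recover its labels;
they cannot show equivalence to perceptual ratings of real dysphonia,
whose labels carry rater noise and richer acoustics.

## Problem sizes

The standard experiment used in tests and examples is a 60-file corpus
(15 per level, 1 s at 25 kHz), chosen to mirror the scale of the
published agreement subsets while keeping a full LOO run (60 refits of
standardization + reduction + 4 GMMs + thresholds) in the tens of
seconds. At this size the best-Grade preset (PCA, 4 GMMs) reaches
~70% efficiency and κ ≈ 0.6, and the best-Roughness preset (LDA, 16
GMMs) separates the synthetic classes completely — synthetic classes
are cleaner than perceptually labeled recordings, so these figures
characterize the pipeline, not clinical performance.

## Known limitations

* Sustained vowels only; the features assume a voiced, quasi-stationary
  carrier and a valid per-frame pitch.
* The separable phase unwrap can differ from quality-guided unwrapping
  on highly disordered phase fields; phase-based MSH/MSW inherit that.
* The EER threshold transfers a frame-level operating point to
  file-level scores; with strongly unbalanced frame counts per file the
  operating point can shift.
* Severity classes of the synthetic generator are nominal levels, not
  calibrated perceptual grades.
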