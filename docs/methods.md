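# Methods

## Problem

A PPG ring rotates freely on the finger. Rotation moves the LED and
photodiode (PD) relative to the finger's internal anatomy and can destroy
signal quality at some positions. The package models this with a Monte
Carlo photon-transport simulation of a layered cylindrical finger, scores
every LED–PD layout by the fraction of detected light that traversed the
capillary-rich microcirculation core, and averages that score over all
rotational positions of a layout. The signal-path half of the package
implements the segment-level signal-quality indices (SQIs), the composite
figure of merit (FoM), and the heart-rate (HR) pipeline that would be used
to validate such a sensor on recorded data, plus a synthetic PPG generator
that provides ground-truthed test signals. Closed-form calculators cover
the analog front-end timing and power budget of the ring hardware.

## Finger model

A finite cylinder (default axial length 20 mm, absorbing end caps) of
outer radius 9.6 mm: epidermis annulus 9.0–9.6 mm, dermis 8.0–9.0 mm, and
a microcirculation disk of radius 8.0 mm. Inside the disk sit five
axis-parallel cylinders: four blood vessels of radius 0.6 mm (volar
"arteries" at ±30° from the volar midline, dorsal "veins" at ±30° from the
dorsal midline, centres at 6.5 mm radius) and a central bone of radius
3 mm. Vessel and bone placement are modelling assumptions — anatomy
references only state that the digital vessels run along the sides of the
finger — and every radius/offset is overridable through a JSON config.
The model is deliberately 3-D: 2-D transport distorts path-length
statistics, and the axial escape through the end caps is physical.

Angles are measured counter-clockwise in the cross-section with 0° at the
volar midline; the model is mirror-symmetric about the volar–dorsal axis,
which the transport results must (and do, statistically) respect.

Optical properties (μa, μs in 1/mm, Henyey–Greenstein g, index n) are per
region and per wavelength (550, 628, 940 nm). The packaged table is
assembled from standard skin/blood/bone optics compilations and is labelled
a literature default: quantitative comparison against any specific
published traversal table additionally requires that study's coefficient
set (and its photon budget), which is why the bundled reference angle table
is used for ranking/symmetry checks rather than absolute-value matching.

## Photon transport

Standard weighted-photon (implicit capture) MCML-style estimator:

- free paths `s = −ln(u)/μt`; at each interaction the weight is multiplied
  by the albedo μs/μt and the absorbed share is tallied;
- Henyey–Greenstein scattering via the closed-form inverse CDF (g = 0
  reduces to isotropic);
- unpolarized Fresnel reflection/refraction wherever the refractive index
  steps (region interfaces and the skin–air surface), with total internal
  reflection beyond the critical angle;
- Russian roulette below weight 1e−4 with survival probability 0.1; the
  roulette weight adjustment is book-kept against the absorbed tally so the
  identity launched = absorbed + escaped + detected holds to rounding
  (verified at 1e−6 relative in every run);
- a per-photon step cap (1e5) guards pathological geometry loops; capped
  photons are tallied as absorbed and counted (their fraction is < 1e−6 in
  default runs).

All geometry is axis-parallel, so boundary search is a 2-D ray–circle
quadratic plus two plane tests, and the kernel compiles with numba. The
LED launches from a 10°-wide, 2 mm-tall patch on the outer surface
(Lambertian into the tissue; a collimated mode exists for closed-form
benchmarks). Detection is any crossing of the outer surface within the PD
patch, at any exit angle (an optional acceptance-angle cut exists, default
off). A photon is tagged as having traversed a region when any transport
sub-step occupies it; the detected weight tagged "microcirculation"
divided by the total detected weight is the layout score
(`micro_fraction`, NaN when nothing is detected — matching the NaN cells
published for non-detecting layouts). Weight-weighted ratios are the
default; a photon-count ratio is available as a flag.

Reproducibility: the kernel draws from per-photon splitmix64 streams keyed
on (run seed, photon index), so a run is bit-identical for a fixed seed
under any batching. Sweep cells use seed `base·1000 + cell_index`, making
sweeps restartable cell by cell. A hand-written counter-based RNG is used
because numpy Generators cannot cross the njit boundary; splitmix64 is a
standard choice for this role in MC codes.

## Layout sweep and ranking

`enumerate_layouts(30°)` yields the 12 × 12 grid: 12 LED–PD angles Δ, each
at 12 rotational positions. `aggregate_by_angle` averages micro_fraction
over the positions sharing one Δ, skipping NaN cells (an angle is NaN only
when all its positions are NaN). `rank_angles` sorts by mean descending,
breaking ties toward lower dispersion (steadier under rotation), then the
smaller angle. Desk-scale default is 1e5 photons/placement; the published
large-scale setting (5e7) is a config value, not the default.

The bundled reference angle table (per-Δ means at 5e7 photons for the same
geometry) reproduces its published structure in our checks: a 60° optimum
at all three wavelengths, mirror symmetry Δ ↔ 360°−Δ, and a green
non-detecting band at 150–210°. Our simulated sweep with the
literature-default coefficients reproduces the qualitative shape (near-zero
traversal at Δ=0, steep rise to ≈1 by 60°, green NaN band at 180°) but
saturates at larger Δ instead of declining; the decline in the published
table depends on the unpublished coefficient set and detector model, so
absolute values are explicitly not desk targets.

## Signal-quality indices and FoM

Records are cut into 6-second segments (N = floor(len/6fs); remainder
dropped) and band-passed 0.5–5 Hz with a zero-phase 4th-order Butterworth
(scipy `butter(2, …, 'bandpass')` — scipy doubles the order for band
filters; zero-phase filtering is chosen to preserve pulse morphology).
Per segment:

- **AC**: mean over the six 1-s windows of (max − min) of the filtered
  signal. **DC**: mean of the raw segment (deliberately unfiltered).
  **PI** = AC/DC, undefined at DC = 0.
- **SNR** (reported, not part of the FoM):
  `10·log10(Σy² / (Σ(y−x_high)² − Σ(y−x_low)²))` with x_high/x_low the raw
  segment high-passed at 0.5 Hz / low-passed at 5 Hz. The denominator is a
  difference of residual powers and is implemented exactly as defined: any
  segment with an appreciable DC pedestal drives it negative, giving NaN.
  The formula is therefore only informative for zero-mean, in-band
  signals, and that is the regime the monotonicity test uses.
- **S_PSD / K_PSD**: with `f[nf] = |rfft(y)[nf]|²` over the NF = T/2+1
  one-sided bins, the sums Σ((f−f̄)/σ_f)³ and Σ(·)⁴ with no 1/NF factor
  (as defined; the session normalization absorbs scale). Flat spectrum →
  undefined.
- **STD_periods / STD_peaks**: one-sided normalized autocorrelation using
  the *unbiased* estimator R[k] = Σ y[t]y[t+k]/(T−k), R[0] = 1, lags
  capped at T/2. The unbiased form is required for the defining property
  that an exactly periodic segment has equal peak heights at every period
  multiple (the biased sum decays linearly in lag and would penalize
  perfectly clean pulses); the lag cap controls the estimator's variance
  growth. Peaks are integer-lag local maxima with prominence ≥ 0.1·R[0]
  and ≥ 0.25 s spacing (both exposed — no standard fixes them). The STDs
  are sample standard deviations of the peak-to-peak intervals and peak
  heights; at least three peaks (two intervals) are required, since a
  single interval carries no dispersion information.

**FoM** = (PI·AC·S_PSD·K_PSD)/(STD_periods·STD_peaks), computed on
per-session min–max-normalized indices mapped to [ε, 1] with ε = 1e−6 (a
constant index normalizes to 1). Segments are excluded ("flagged") when
any ingredient is undefined or when either periodicity SD is exactly zero:
a zero denominator factor makes the ratio meaningless, and at a 100 Hz
sampling grid identical quantized peak intervals occur by chance, so such
segments would otherwise dominate the session mean through the ε floor.
The session summary is mean ± SD of the per-segment FoM. Because the
normalization is per session, FoM magnitudes are relative quality scores
within a session; absolute published FoM tables are not reproducible
without the same normalization cohort, and are not targets.

Known limitation: with min–max normalization over ~20 segments, the
session mean is dominated by the segments at the normalization extremes,
so the clean-vs-corrupted ordering is statistically firm only when the
corruption is strong. The packaged comparison condition is additive white
noise at −12 dB relative to the pulsatile power plus 20 motion-artifact
bursts/min; at that level the clean half outscored the corrupted half in
395 of 400 validation sessions (and in all ten fixed-seed test sessions).
Mild corruption (e.g. −10 dB noise alone) can lose the ordering through
noise-inflated AC/PI and quantization ties — an intrinsic property of this
FoM, not of the implementation.

## Heart rate

0.5–8 Hz zero-phase 4th-order Butterworth, then systolic peak picking with
an adaptive threshold: half of a rolling 3-s 90th-percentile envelope,
0.25 s refractory spacing, and a small relative-prominence floor so a flat
record yields no peaks. HR = 60/mean(IBI); fewer than two peaks, or a
rate outside (20, 300) bpm, flags the estimate. The estimate is invariant
under amplitude scaling, and the envelope lets beats of alternating
amplitude count fully. Windowed series use 10-s windows with 5-s hop
(both exposed). Scoring against a reference series reports MAE (bpm) and
the percentage of windows within 3 bpm. On clean synthetic 60-s records
the recovery error is ≲ 0.05 bpm across 50–120 bpm — this validates the
pipeline arithmetic, not clinical accuracy against polysomnography.

## Synthetic PPG generator

Per beat, a systolic Gaussian (σ = 0.09·IBI) plus a dicrotic Gaussian at
0.35·IBI delay with relative amplitude 0.35 (σ = 0.14·IBI) — the common
two-Gaussian PPG surrogate. Beat onsets carry Gaussian IBI jitter
(default 2% of the mean interval, a conservative resting short-window
variability). Defaults describe a resting finger recording at 100 Hz for
60 s: DC 1000, pulsatile peak-to-peak 20 (PI = 0.02), 0.25 Hz respiratory
drift at amplitude 10; additive white noise (quoted as SNR against the
pulsatile power, so clean/noisy orderings are well defined) and 0.25-s
Gabor-like artifact bursts at 5× pulse amplitude are opt-in. The
generator emits ground truth (peak indices at local maxima of the
noiseless signal, true beat-interval rate, true AC/DC), and is
deterministic per seed. It does not emulate subject-specific morphology,
arrhythmia, wavelength-dependent perfusion, or sensor nonlinearity; tests
that pass on it certify the pipelines' arithmetic and robustness logic
only.

## Front-end calculators

Pure closed-form arithmetic: duty cycle = ON-time × firing rate (70 μs at
100 Hz → 0.7%); ON-time budget = ADC sampling (30 μs) + TIA settling
(20 μs) + LED/PD setup (10 μs) + damping margin (10 μs); minimum TIA
settling = 8·R_F·C_F (8 × 2.5 μs at R_F = 1 MΩ, C_F = 2.5 pF); effective
signal-chain bandwidth = f_RC × f_SP(ADC) × T_SAMP (100 Hz × 2.5 kHz ×
30 μs = 7.5 Hz, i.e. 25% margin over the 6 Hz requirement — f_RC is the
unique value consistent with the other three constants); module current
sum and battery life (594.5 μA total from the six-module budget; 22 mAh →
37.0 h ≥ 30 h). The TIA compensation capacitor is provided in two modes:
`stability`, C_F = √(C_i/(2π·R_F·UGB)), the dimensionally consistent
pole-matching form whose values land in the published 2.5–20 pF range; and
`literal`, C_F = C_i/(2π·R_F·UGB), the formula exactly as printed in the
design reference, which is dimensionally inconsistent (≈1e−24 F) and kept
for fidelity. Default is `stability`; the discrepancy is surfaced, never
silently corrected. The 179 μA LED figure in the module budget is treated
as an input: it is not derivable from 0.7% duty × the stated 2/8 mA drive
currents (that product is ≈140 μA), so the calculator reports whatever the
inputs imply and never hard-codes the published value.

## Problem sizes

Default test and acceptance problem sizes are desk-scale by design: 1e4–1e5
photons per transport run (the mirror-symmetry check uses 1e5/placement on
a 90° grid; the full 30° sweep uses 1e4/cell), 1e6 draws for the
scattering-moment checks, 60-s records at 100 Hz for the signal path, and
10 sessions for the FoM ordering experiment. Statistical assertions are
phrased in standard errors (3·SE), so they remain valid at any photon
budget; the published 5e7-photon setting is available through
`TransportConfig(n_photons=...)`.
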