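# Methods

This note documents the models and procedures implemented in `beatflow`,
the parameters that matter, and the numerical choices made where the
design was genuinely open.

## Two-stage block-matching optical flow

A displacement field between a reference frame and a moving frame is
estimated in two passes:

1. **Coarse pass.** The reference frame is divided into overlapping
   square tiles (default 64 px, step = tile/2, i.e. 50% overlap). For
   each tile, every integer shift within ±`search_radius` (default 16 px)
   is scored by the Euclidean distance between intensity patches (sum of
   squared differences on raw grayscale; no normalisation). The minimum
   wins; ties are broken by smallest shift magnitude, then
   lexicographically by (drow, dcol). Candidate windows leaving the image
   are skipped; a tile with no remaining candidate is flagged invalid
   rather than raising.
2. **Spline smoothing.** One thin-plate spline per displacement component
   is fit to the valid coarse vectors (invalid tiles excluded),
   minimising `Σ(f(xᵢ) − vᵢ)² + λ wᵀKw` with kernel `U(r) = r² log r` and
   an unpenalised affine part. At λ = 0 the spline interpolates exactly;
   affine fields are reproduced exactly for any λ. By default λ is chosen
   per field by generalized cross-validation over a log grid
   (10⁻⁴…10³); tests pin λ explicitly.
3. **Fine pass.** Smaller tiles (default 32 px) repeat the search in a
   ±`fine_radius` (default 4 px) window around the rounded spline
   prediction; the final vector is prediction + residual, so uniform
   motions far beyond the fine radius are still recovered exactly.

Matching is integer-pixel by design; sub-pixel structure enters only
through the spline. No parabolic peak interpolation is applied. The
coarse search is windowed (±16 px) rather than whole-image because
monolayer displacements are small relative to the frame; the radius is
configurable where larger motions are expected.

Two numerically equivalent scoring engines are provided: a direct
sum-of-squares engine (exact; used for small candidate sets and in oracle
tests) and an FFT cross-correlation engine with integral-image window
sums (used for large searches; agrees with the direct engine to ~1e-12
relative). Scores within `1e-8·(Σtile² + 1)` of the minimum are treated
as tied so that the deterministic tie-break rule is robust to FFT
round-off; in particular a perfect match always yields the zero shift and
a score of exactly 0, which guarantees the zero-motion law (identical
frames → exactly zero fields at every stage).

Coordinates are (row, col), 0-based; a displacement (drow, dcol) maps a
reference position to its position in the moving frame.

## Reference selection and beat pattern

The resting reference frame t\* minimises a cheap motion measure V(t):
the spatial mean displacement magnitude between consecutive frames,
computed with the coarse pass only (the last value is duplicated so the
trace aligns with frames). The earliest minimiser wins ties. The
published criterion V(t) ≥ V(t\*) only constrains the minimiser; the
choice of V as consecutive-frame coarse-flow magnitude is ours — it is
cheap and monotone in true motion.

The beat pattern is D(t) = ⟨|d(t, x)|⟩ₓ, the mean Euclidean norm over
valid grid centers (a frame with no valid centers yields a flagged NaN).
D(t\*) = 0 exactly, since the reference is compared against itself.

## Spectral analysis

D(t) is mean-subtracted (no taper window by default) and transformed with
the real DFT. Power is reported one-sided as |X_k|²/N with interior bins
doubled, so the total power equals N·Var(D) exactly (Parseval); the DC
bin is zero by construction. The dominant frequency is the bin-center
frequency of the maximum power at or above `min_freq` (default 0.05 Hz,
excluding drift), ties resolving to the lowest frequency. Frequency
resolution is 1/(N·Δt); with the default 20 s recordings that is 0.05 Hz.
For non-sinusoidal beats, harmonics appear at 2f, 3f, … — verified
against numerically integrated Fourier-series coefficients of the pulse
waveform.

## Convergence mapping

Convergence is minus the divergence of the displacement field,
`−(∂d_row/∂row + ∂d_col/∂col)`, by second-order central differences on
the tile grid (one-sided at borders, which are flagged, as are centers
whose stencil touches an invalid vector). Because the field is a
displacement relative to the reference state, units are px per grid step
**per frame interval**, not a per-second velocity. Uniform translation is
exactly invisible; contraction (inward flow) is positive, expansion
negative; the map is linear in the field. By default the divergence is
taken on the TPS-smoothed field evaluated on the grid, suppressing the
integer-matching noise that differentiation amplifies; the raw-field
option is retained.

For a single Gaussian center of amplitude A and radius σ the analytic
convergence is `A·b(t)/σ · (2 − r²/σ²) · exp(−r²/2σ²)`, peaking at
`2Ab/σ`. The 16-px stencil underestimates that sharp peak (≈ 0.7× at
σ ≈ 43 px); this flattening is systematic and cancels in ratios, which is
why the amplitude-doubling check is a ratio test.

Contractile centers are local maxima (8-neighbourhood) of the
time-maximum convergence map above a threshold, greedily pruned to a
minimum separation and sorted by peak convergence. The default threshold
is 3× the median absolute convergence of the rest frames (the quartile of
frames with least mean convergence), with a floor of 10% of the global
peak so that the noiseless limit — where the rest median is exactly
zero — does not produce spurious weak calls. Time-max is the default
reduction; time-mean and single-frame maps are available through the
returned per-frame series.

## Field-potential metrics

- **Spike detection** operates on |voltage − running median| (the running
  median is computed on a decimated grid for speed; window 50 ms), so
  either depolarisation polarity works and all timing metrics are
  invariant under voltage rescaling. Peaks must be ≥ `refractory`
  (default 0.2 s) apart and have prominence ≥ `prominence_frac` (default
  0.3) of the largest prominence; a trace whose largest prominence is
  below 8× the robust noise scale (MAD/0.6745) is declared spike-free, so
  pure noise is never "detected".
- **Beat period**: successive inter-spike intervals; mean and population
  SD.
- **Spike amplitude**: max − min voltage within ±window/2 (default 50 ms)
  of each spike; a window reaching the adjacent beat is a parameter
  error.
- **FPD**: per beat, the delay from the spike to the extremum of the
  smoothed (Gaussian, σ = 8 ms), baseline-subtracted repolarisation wave
  within (spike + 50 ms, spike + 0.8×beat period). Beats whose extremum
  is below 5% of the spike amplitude or sits at the window edge are
  flagged undetected rather than guessed.
- **FPDc**: Fridericia cube-root correction FPD/(beat period in s)^⅓ —
  identity at a 1 s period, strictly decreasing in the period. A Bazett
  (square-root) variant is provided but off by default.
- **Irregularity**: CV = SD/mean of the intervals (population SD
  convention); a well is flagged arrhythmic when CV > 0.15. This
  transparent rule is a documented stand-in for proprietary arrhythmia
  classifiers; the 0.15 default cleanly separates alternans-scale
  alternation (CV ≈ 0.2 for a 0.2 s alternans on a 1 s period) from
  ordinary beat jitter (CV ≈ 0.02).
- **Drug contrast**: treated/baseline ratios per metric with direction
  labels (beat-period ratio < 1 → "chronotropy up"; FPDc ratio > 1 →
  "prolonged", the in vitro analogue of QT prolongation).

## Synthetic data: what it emulates, and what it does not

**Videos.** The texture is Gaussian-blurred seeded white noise rescaled
to [0, 1]; the blur sigma (`texture_granularity`, default 4 px) sets the
spatial correlation length. It stands in for phase-contrast monolayer
texture but models none of its cell-scale structure. Contraction is a sum
of Gaussian centers, each displacing tissue radially inward by
`−A·b(t)·(x−c)/σ·exp(−|x−c|²/2σ²)`, driven by a waveform b(t) ∈ [0, 1]
with b(0) = 0: `sine` (sin²(πft), a pure tone in D(t)) or
`half_wave_pulse` (a raised-cosine pulse of width duty×period, which
rests between beats and carries harmonics). Frames are rendered by
backward warping — each output pixel samples the texture at x − d(t, x)
with bilinear interpolation — so the stored analytic field is the
*sampling* displacement and all comparisons use it consistently. Additive
Gaussian intensity noise is per-frame seeded. Defaults (128×128 px,
30 fps, 20 s, one center of amplitude 4 px and radius ≈ 43 px) are
desk-scale configuration choices, not claims about any particular
instrument: real recordings' frame rates, magnification, out-of-focus
drift, illumination flicker and cell-level texture dynamics are not
modeled, so passing tests demonstrate correctness of the *analysis*, not
robustness to every property of real data.

**Field potentials.** Each beat contributes a biphasic spike (dominant
Gaussian peak of width 1.5 ms at the nominal spike time, a 30% trough
10 ms later; realized peak-to-trough = `spike_amplitude` to within the
small overlap) and a repolarisation bump (15% of the spike amplitude,
σ = 25 ms) peaking exactly `fpd` after the spike. Intervals are
`beat_period + jitter ∓ alternans_delta` (alternating sign, minus
first), with Gaussian sampling noise on top. Default sampling rate is
5 kHz, comfortably above the 1 kHz floor. Real MEA features not modeled:
conduction delays across electrodes, T-wave morphology variants,
electrode drift and 50/60 Hz interference.

## Problem sizes used in tests

The acceptance suite runs the full pipeline at the study conditions
(128×128 px, 30 fps, 20 s videos; 60 s field-potential traces at 5 kHz;
256×256 px pairs for the flow oracle). Unit tests use shorter recordings
(2–10 s) of the same scenes, which already exercise every code path; one
shared 10 s recording is computed once per session and reused across
flow, beat, and convergence tests.

## Known limitations

- Matching is integer-pixel; displacement amplitudes below ~1 px are
  visible only through the spline smoothing and quantization makes
  per-frame values coarse (the beat frequency is still recovered exactly
  in such scenes).
- GCV smoothing selection is per-frame and can over-smooth sharp
  contraction foci that are under-resolved by the tile grid; peak
  convergence values are therefore best interpreted relatively (ratios,
  time courses) rather than as absolute strains.
- The FPD detector assumes a single dominant repolarisation extremum per
  beat; biphasic repolarisation waves would need a different rule.
- The irregularity CV flag detects interval-scale irregularity
  (alternans, skipped beats) but not amplitude alternans or conduction
  block patterns.
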