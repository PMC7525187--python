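# beatflow

Video-based contractility analysis and multielectrode-array (MEA)
field-potential metrics for beating cardiomyocyte cultures — e.g. hiPSC-CM
monolayers or engineered cardiac patches — with a synthetic-data module
that makes every stage verifiable against exact ground truth.

## What it computes

**Contractility from videomicroscopy.** Given a multi-page TIFF stack of a
beating cell layer, the pipeline:

1. selects a resting **reference frame t\*** — the frame with minimal
   consecutive-frame motion, V(t) ≥ V(t\*);
2. estimates **displacement fields d(t, x)** of every frame relative to
   the reference by two-stage block-matching PIV: overlapping 64-px tiles
   matched by exhaustive integer-pixel Euclidean (SSD) search, the
   scattered vectors interpolated/denoised by a **thin-plate spline**, and
   a second pass of 32-px tiles searching ±4 px around the spline
   prediction;
3. reduces each field to the **beat pattern D(t) = ⟨|d(t, x)|⟩ₓ**, the
   spatial mean displacement magnitude;
4. computes the DFT **power spectrum** of D(t) (power = |X_k|²/N,
   one-sided) and reports the dominant beat frequency f; non-sinusoidal
   beats show harmonics at 2f, 3f, …;
5. maps **convergence = −∇·d(t, x)** on the tile grid, which cancels
   passive translation and localizes **contractile centers**, scored by
   their peak convergence.

**Field-potential metrics from MEA traces.** Given a (time, voltage) CSV:
spike times, beat period, peak-to-trough spike amplitude, field potential
duration (FPD, the spike-to-repolarisation interval — the in vitro QT
analogue), the Fridericia rate correction **FPDc = FPD/(beat period)^⅓**,
a beat-period irregularity flag (CV of inter-beat intervals), and
baseline-vs-treated contrasts (chronotropy, FPDc prolongation, amplitude).

**Synthetic data.** `SceneSpec` renders a textured monolayer warped by
periodic Gaussian contraction centers (analytic d(t, x) stored alongside);
`FPSpec` synthesizes MEA-like traces with controllable period, FPD,
amplitude, jitter, and alternans. Both are pure functions of their spec,
including its seed.

## Worked example

```python
import numpy as np
import beatflow as bf

# a 128x128, 30 fps, 20 s synthetic recording beating at 1 Hz
spec = bf.SceneSpec(beat_frequency=1.0, duration=20.0, texture_seed=0)
video = bf.generate_video(spec)

motion = bf.frame_motion(video.sequence)          # V(t), picks t*
fields = bf.compute_flow(video.sequence, motion.t_star)
trace = bf.beat_pattern(fields, video.sequence.frame_interval)
spectrum = bf.power_spectrum(trace)
f = bf.dominant_frequency(spectrum)
maps, strength = bf.convergence_series(fields)
calls = bf.locate_centers(maps)
```

This prints (via the obvious `print` statements):

```
reference frame t* = 0
dominant beat frequency = 1.00 Hz (bin width 0.050 Hz)
max beat amplitude D(t) = 1.97 px
peak convergence = 0.130 per frame
contractile centers: [((64.0, 64.0), 0.13)]
```

The reference frame falls in a rest phase, the spectral peak sits exactly
on the true 1 Hz beat frequency, and the single contractile center is
called at the image center where the synthetic contraction focus was
placed. On the field-potential side:

```python
fp_spec = bf.FPSpec(beat_period=1.04, fpd=0.40, duration=30.0, noise_sd=2.0, seed=0)
fp_trace, truth = bf.generate_field_potential(fp_spec)
print(bf.compute_metrics(fp_trace).as_dict())
# mean_beat_period_s = 1.040, mean_fpd_s = 0.400, fpdc_s = 0.395, arrhythmic = False
```

Both the 1.04 s beat period and the 0.40 s FPD are recovered to three
decimals at 2% noise, and the Fridericia-corrected FPDc = 0.40/1.04^⅓.

A CLI mirrors the library: `beatflow simulate video|fp`, `beatflow flow`,
`beatflow beats`, `beatflow spectrum`, `beatflow converge`, `beatflow fp`,
`beatflow fp-contrast`, `beatflow run-all` (see `--help`).

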