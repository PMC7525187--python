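"""Beat-pattern extraction and spectral analysis of contractility videos.

The reduction chain is: pick a resting reference frame t* (the global
minimum of a cheap consecutive-frame motion measure), express every frame
as a displacement field relative to that reference, average the vector
magnitudes spatially into the beat pattern D(t), and characterise the
beating by the discrete Fourier power spectrum of D(t).  For
non-sinusoidal beats the spectrum carries harmonics at integer multiples
2f, 3f, ... of the fundamental beat frequency f.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import InputError
from .flow import DisplacementField, ImageSequence, coarse_field

__all__ = [
    "MotionTrace",
    "BeatTrace",
    "PowerSpectrum",
    "frame_motion",
    "select_reference",
    "beat_pattern",
    "power_spectrum",
    "dominant_frequency",
]


@dataclass
class MotionTrace:
    """Per-frame motion magnitude V(t) with the selected reference index."""

    values: np.ndarray  # (T,) mean consecutive-frame displacement magnitude
    t_star: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class BeatTrace:
    """The beat pattern D(t): spatial mean displacement magnitude per frame."""

    values: np.ndarray  # (T,) pixels; NaN where a frame had no valid vectors
    times: np.ndarray  # (T,) seconds
    reference: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.shape != self.times.shape:
            raise InputError("values and times must have matching shapes")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class PowerSpectrum:
    """One-sided DFT power spectrum of a beat trace.

    ``power[k]`` is ``|X_k|^2 / N`` with interior bins doubled, so the sum
    over bins equals N times the population variance of the mean-subtracted
    signal (Parseval).  ``fundamental`` and ``harmonic_frequencies`` are
    filled in by :func:`dominant_frequency`.
    """

    frequencies: np.ndarray  # Hz, DFT bin centers up to Nyquist
    power: np.ndarray
    n_samples: int
    fundamental: float | None = None
    harmonic_frequencies: np.ndarray = dataclass_field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def frame_motion(sequence: ImageSequence, **coarse_kwargs) -> MotionTrace:
    """Cheap per-frame motion measure from consecutive-frame coarse flow.

    V(t) is the spatial mean displacement magnitude between frames t and
    t+1 estimated with the coarse matching stage only; the last value is
    duplicated so indexing matches the frames.  The selection criterion for
    the resting reference is V(t) >= V(t*) for all t, earliest minimiser.
    """
    frames = sequence.frames
    T = len(sequence)
    V = np.empty(T)
    for t in range(T - 1):
        fld = coarse_field(frames[t], frames[t + 1], **coarse_kwargs)
        V[t] = fld.mean_magnitude()
    V[T - 1] = V[T - 2]
    if np.isnan(V).any():
        raise InputError("motion trace contains frames with no valid tiles")
    return MotionTrace(values=V, t_star=int(np.argmin(V)))


def select_reference(motion: MotionTrace) -> int:
    """Earliest frame index achieving the minimum of V(t)."""
    return int(np.argmin(motion.values))


def beat_pattern(
    fields: list[DisplacementField], frame_interval: float
) -> BeatTrace:
    """Reduce displacement fields to D(t), the spatial mean of |d(t, x)|.

    Invalid grid centers are excluded from the average; a frame with no
    valid centers yields NaN (flagged missing).  D is exactly zero at the
    reference frame, which was compared against itself.
    """
    if not fields:
        raise InputError("no displacement fields given")
    ref = fields[0].reference
    grid = fields[0].grid
    for f in fields:
        if f.grid is not grid and (
            f.grid.shape != grid.shape or f.grid.tile_size != grid.tile_size
        ):
            raise InputError("fields must share one grid")
        if f.reference != ref:
            raise InputError("fields must share one reference frame")
    D = np.array([f.mean_magnitude() for f in fields])
    times = np.arange(len(fields)) * frame_interval
    return BeatTrace(values=D, times=times, reference=int(ref) if ref is not None else 0)


def power_spectrum(trace: BeatTrace) -> PowerSpectrum:
    """One-sided DFT power spectrum of the mean-subtracted beat pattern.

    No taper window is applied by default; the DC component is removed by
    mean subtraction before the transform.
    """
    D = trace.values
    if D.size < 8:
        raise InputError("need at least 8 samples for a spectrum")
    if np.isnan(D).any():
        raise InputError("beat trace contains missing values")
    dt = np.diff(trace.times)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise InputError("non-uniform timestamps")
    x = D - D.mean()
    N = x.size
    X = np.fft.rfft(x)
    power = (X.real**2 + X.imag**2) / N
    power[0] = 0.0  # DC is exactly zero after mean subtraction
    # fold the negative-frequency half in, so sum(power) = N * var(x)
    if N % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(N, d=trace.frame_interval)
    return PowerSpectrum(frequencies=freqs, power=power, n_samples=N)


def dominant_frequency(spectrum: PowerSpectrum, min_freq: float = 0.05) -> float:
    """Bin-center frequency of the maximum power at or above ``min_freq``.

    Ties resolve to the lowest frequency.  Also records the fundamental and
    its in-band harmonics (2f, 3f, ...) on the spectrum object.
    """
    band = spectrum.frequencies >= min_freq
    if not band.any():
        raise InputError("no spectral bins at or above min_freq")
    idx = np.flatnonzero(band)
    k = idx[int(np.argmax(spectrum.power[idx]))]
    f = float(spectrum.frequencies[k])
    spectrum.fundamental = f
    nyquist = spectrum.frequencies[-1]
    if f > 0:
        n_h = int(nyquist // f)
        spectrum.harmonic_frequencies = f * np.arange(1, max(n_h, 1) + 1)
    return f
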