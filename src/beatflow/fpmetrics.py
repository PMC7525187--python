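"""Field-potential metrics for multielectrode-array (MEA) recordings.

Implements the per-well quantities commonly reported for spontaneously
beating cardiomyocyte cultures: beat period, field potential duration
(FPD, the spike-to-repolarisation interval — an in vitro QT analogue),
the Fridericia rate-corrected FPDc = FPD / (beat period)^(1/3), spike
amplitude, and a beat-period irregularity flag (coefficient of variation
of the inter-beat intervals against a threshold).

Spike detection operates on the absolute deviation from a running median,
so either depolarisation polarity works and all timing metrics are
invariant under voltage rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, medfilt

from .errors import MetricUndefinedError, ParameterError

__all__ = [
    "FieldPotentialTrace",
    "BeatMetrics",
    "ContrastRecord",
    "detect_spikes",
    "beat_periods",
    "spike_amplitude",
    "detect_fpd",
    "fridericia_fpdc",
    "irregularity",
    "compute_metrics",
    "drug_contrast",
]

DEFAULT_CV_THRESHOLD = 0.15


@dataclass
class FieldPotentialTrace:
    """A uniformly sampled single-channel field-potential recording."""

    time: np.ndarray  # seconds
    voltage: np.ndarray  # signal units
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ParameterError("time and voltage must be matching 1-D arrays")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    @classmethod
    def from_arrays(cls, voltage: np.ndarray, sampling_rate: float) -> "FieldPotentialTrace":
        voltage = np.asarray(voltage, dtype=np.float64)
        t = np.arange(voltage.size) / sampling_rate
        return cls(t, voltage, sampling_rate)


@dataclass
class BeatMetrics:
    """Per-well beat metrics derived from one field-potential trace."""

    spike_times: np.ndarray
    beat_periods: np.ndarray
    mean_beat_period: float
    period_sd: float
    spike_amplitudes: np.ndarray
    mean_spike_amplitude: float
    fpd_per_beat: np.ndarray  # NaN where the repolarisation wave was undetected
    mean_fpd: float
    fpdc: float  # Fridericia-corrected mean FPD
    irregularity_cv: float
    arrhythmic: bool
    status: str = "ok"
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_beats": int(self.spike_times.size),
            "mean_beat_period_s": self.mean_beat_period,
            "beat_period_sd_s": self.period_sd,
            "mean_spike_amplitude": self.mean_spike_amplitude,
            "mean_fpd_s": self.mean_fpd,
            "fpdc_s": self.fpdc,
            "irregularity_cv": self.irregularity_cv,
            "arrhythmic": bool(self.arrhythmic),
            "status": self.status,
        }


def _running_median(voltage: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Running median baseline, computed on a decimated grid for speed."""
    dec = max(1, int(fs * window_s / 25))
    sub = voltage[::dec]
    k = int(round(window_s * fs / dec))
    k = max(3, k | 1)  # odd
    if sub.size < k:
        return np.full_like(voltage, np.median(voltage))
    med = medfilt(sub, k)
    idx = np.arange(voltage.size)
    return np.interp(idx, idx[::dec], med)


def detect_spikes(
    trace: FieldPotentialTrace,
    prominence_frac: float = 0.3,
    refractory: float = 0.2,
    baseline_window: float = 0.05,
    min_snr: float = 8.0,
) -> np.ndarray:
    """Detect depolarisation spike times.

    Local maxima of ``|voltage - running median|`` whose prominence is at
    least ``prominence_frac`` times the largest prominence in the trace,
    separated by at least ``refractory`` seconds.  A trace whose largest
    prominence is below ``min_snr`` times the robust noise scale (median
    absolute deviation) is treated as spike-free.  Returns spike times in
    seconds; an empty array (with a warning) if nothing crosses threshold.
    """
    if not 0 < prominence_frac <= 1:
        raise ParameterError("prominence_frac must lie in (0, 1]")
    if refractory <= 0:
        raise ParameterError("refractory must be positive")
    fs = trace.sampling_rate
    baseline = _running_median(trace.voltage, fs, baseline_window)
    dev = np.abs(trace.voltage - baseline)
    distance = max(1, int(round(refractory * fs)))
    peaks, props = find_peaks(dev, distance=distance, prominence=0.0)
    if peaks.size == 0:
        warnings.warn("no spikes detected in trace", stacklevel=2)
        return np.empty(0)
    prominences = props["prominences"]
    noise_scale = float(np.median(dev)) / 0.6745  # MAD -> sigma for Gaussian noise
    if prominences.max() < min_snr * noise_scale:
        warnings.warn("no spikes detected in trace", stacklevel=2)
        return np.empty(0)
    keep = prominences >= prominence_frac * prominences.max()
    times = trace.time[peaks[keep]]
    if times.size == 0:
        warnings.warn("no spikes detected in trace", stacklevel=2)
    return times


def beat_periods(spike_times: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Successive inter-spike intervals with their mean and population SD."""
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size < 2:
        raise MetricUndefinedError("beat period requires at least 2 spikes")
    periods = np.diff(spike_times)
    return periods, float(periods.mean()), float(periods.std())


def spike_amplitude(
    trace: FieldPotentialTrace,
    spike_times: np.ndarray,
    window: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Peak-to-trough voltage within ``+/-window/2`` of each spike time."""
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size == 0:
        raise MetricUndefinedError("no spikes to measure")
    if spike_times.size >= 2 and window >= np.diff(spike_times).min():
        raise ParameterError("amplitude window overlaps the adjacent beat")
    fs = trace.sampling_rate
    hw = int(round(window / 2 * fs))
    amps = np.empty(spike_times.size)
    for i, ts in enumerate(spike_times):
        k = int(round((ts - trace.time[0]) * fs))
        lo, hi = max(0, k - hw), min(trace.voltage.size, k + hw + 1)
        seg = trace.voltage[lo:hi]
        amps[i] = float(seg.max() - seg.min())
    return amps, float(amps.mean())


def detect_fpd(
    trace: FieldPotentialTrace,
    spike_times: np.ndarray,
    search_start: float = 0.05,
    search_frac: float = 0.8,
    smooth_sigma: float = 0.008,
    min_fraction: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Per-beat field potential duration and its mean over detected beats.

    For each spike, the FPD is the delay to the extremum of the smoothed,
    baseline-subtracted repolarisation wave inside the window
    ``(spike + search_start, spike + search_frac * beat_period)``.  Beats
    whose extremum is below ``min_fraction`` of the spike amplitude, sits
    at the window edge, or whose window leaves the trace are flagged NaN.
    """
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size == 0:
        raise MetricUndefinedError("no spikes given")
    fs = trace.sampling_rate
    baseline = _running_median(trace.voltage, fs, 0.2)
    smoothed = gaussian_filter1d(trace.voltage - baseline, smooth_sigma * fs)
    amps, mean_amp = spike_amplitude(trace, spike_times)
    floor = min_fraction * mean_amp
    if spike_times.size >= 2:
        typical = float(np.median(np.diff(spike_times)))
    else:
        typical = trace.duration
    fpd = np.full(spike_times.size, np.nan)
    t0 = trace.time[0]
    for i, ts in enumerate(spike_times):
        period = (spike_times[i + 1] - ts) if i + 1 < spike_times.size else typical
        lo = int(round((ts - t0 + search_start) * fs))
        hi = int(round((ts - t0 + search_frac * period) * fs))
        if lo >= hi or hi > smoothed.size:
            continue  # incomplete beat at the end of the trace
        seg = np.abs(smoothed[lo:hi])
        j = int(seg.argmax())
        if seg[j] < floor or j == 0 or j == seg.size - 1:
            continue  # no detectable repolarisation extremum
        fpd[i] = trace.time[lo + j] - ts
    detected = fpd[np.isfinite(fpd)]
    mean_fpd = float(detected.mean()) if detected.size else float("nan")
    return fpd, mean_fpd


def fridericia_fpdc(fpd: float | np.ndarray, beat_period: float | np.ndarray):
    """Fridericia cube-root rate correction: FPDc = FPD / (beat period)^(1/3).

    Both arguments are in seconds; FPDc equals FPD exactly at a 1 s beat
    period and is strictly decreasing in the beat period for fixed FPD.
    """
    fpd = np.asarray(fpd, dtype=np.float64)
    beat_period = np.asarray(beat_period, dtype=np.float64)
    if np.any(fpd <= 0) or np.any(beat_period <= 0):
        raise ParameterError("fpd and beat_period must be positive")
    out = fpd / np.cbrt(beat_period)
    return float(out) if out.ndim == 0 else out


def bazett_fpdc(fpd: float | np.ndarray, beat_period: float | np.ndarray):
    """Bazett square-root correction, offered as an alternative convention."""
    fpd = np.asarray(fpd, dtype=np.float64)
    beat_period = np.asarray(beat_period, dtype=np.float64)
    if np.any(fpd <= 0) or np.any(beat_period <= 0):
        raise ParameterError("fpd and beat_period must be positive")
    out = fpd / np.sqrt(beat_period)
    return float(out) if out.ndim == 0 else out


def irregularity(
    periods: np.ndarray, cv_threshold: float = DEFAULT_CV_THRESHOLD
) -> tuple[float, bool]:
    """Beat-period irregularity: CV of intervals and an arrhythmia flag.

    CV uses the population SD convention (divide by n).  The flag is a
    transparent stand-in for proprietary arrhythmia classifiers: a well is
    called arrhythmic when CV exceeds ``cv_threshold`` (default 0.15),
    which separates alternans-scale alternation from ordinary jitter.
    """
    periods = np.asarray(periods, dtype=np.float64)
    if periods.size < 3:
        raise MetricUndefinedError("irregularity requires at least 3 periods")
    mean = periods.mean()
    if mean <= 0:
        raise MetricUndefinedError("mean beat period must be positive")
    cv = float(periods.std() / mean)
    return cv, bool(cv > cv_threshold)


def compute_metrics(
    trace: FieldPotentialTrace,
    prominence_frac: float = 0.3,
    refractory: float = 0.2,
    amplitude_window: float = 0.05,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> BeatMetrics:
    """Run the full metric chain on one trace and assemble a BeatMetrics."""
    if trace.duration < 2.0:
        raise ParameterError("metric computation needs at least 2 s of signal")
    spikes = detect_spikes(trace, prominence_frac, refractory)
    if spikes.size < 2:
        raise MetricUndefinedError("fewer than 2 spikes detected")
    periods, mean_bp, sd_bp = beat_periods(spikes)
    amps, mean_amp = spike_amplitude(trace, spikes, amplitude_window)
    fpd, mean_fpd = detect_fpd(trace, spikes)
    notes: list[str] = []
    if np.isnan(fpd).any():
        notes.append(f"{int(np.isnan(fpd).sum())} beats without detectable repolarisation")
    fpdc = (
        fridericia_fpdc(mean_fpd, mean_bp) if np.isfinite(mean_fpd) else float("nan")
    )
    if periods.size >= 3:
        cv, arrhythmic = irregularity(periods, cv_threshold)
    else:
        cv, arrhythmic = float("nan"), False
        notes.append("too few periods for irregularity")
    return BeatMetrics(
        spike_times=spikes,
        beat_periods=periods,
        mean_beat_period=mean_bp,
        period_sd=sd_bp,
        spike_amplitudes=amps,
        mean_spike_amplitude=mean_amp,
        fpd_per_beat=fpd,
        mean_fpd=mean_fpd,
        fpdc=fpdc,
        irregularity_cv=cv,
        arrhythmic=arrhythmic,
        notes=notes,
    )


@dataclass
class ContrastRecord:
    """Fold-changes of treated vs baseline metrics with direction labels."""

    fold_change: dict[str, float]
    direction: dict[str, str]
    missing: list[str]

    def as_dict(self) -> dict:
        return {
            "fold_change": self.fold_change,
            "direction": self.direction,
            "missing": self.missing,
        }


def _ratio(a: float, b: float) -> float:
    if not (np.isfinite(a) and np.isfinite(b)) or b == 0:
        return float("nan")
    return a / b


def drug_contrast(baseline: BeatMetrics, treated: BeatMetrics) -> ContrastRecord:
    """Compare treated vs baseline wells: ratios and qualitative directions.

    Beat-period fold-change below 1 means faster beating ("chronotropy
    up"); FPDc fold-change above 1 means a prolonged repolarisation
    interval, the in vitro analogue of QT prolongation.
    """
    fc = {
        "beat_period": _ratio(treated.mean_beat_period, baseline.mean_beat_period),
        "fpdc": _ratio(treated.fpdc, baseline.fpdc),
        "spike_amplitude": _ratio(
            treated.mean_spike_amplitude, baseline.mean_spike_amplitude
        ),
    }
    missing = [k for k, v in fc.items() if not np.isfinite(v)]
    direction: dict[str, str] = {}
    bp = fc["beat_period"]
    if np.isfinite(bp):
        direction["chronotropy"] = "up" if bp < 1 else ("down" if bp > 1 else "unchanged")
    f = fc["fpdc"]
    if np.isfinite(f):
        direction["fpdc"] = (
            "prolonged" if f > 1 else ("shortened" if f < 1 else "unchanged")
        )
    a = fc["spike_amplitude"]
    if np.isfinite(a):
        direction["amplitude"] = (
            "increased" if a > 1 else ("decreased" if a < 1 else "unchanged")
        )
    if baseline.arrhythmic != treated.arrhythmic:
        direction["arrhythmia"] = (
            "emerged" if treated.arrhythmic else "resolved"
        )
    return ContrastRecord(fold_change=fc, direction=direction, missing=missing)
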