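"""Ground-truth-known synthetic data: beating-monolayer videos and MEA traces.

The video generator emulates phase-contrast recordings of a contracting
cardiomyocyte monolayer: a random texture with a controllable spatial
correlation length is warped by a periodic, spatially localised contraction
field (one or more Gaussian "contractile centers" pulling tissue radially
inward), with optional additive Gaussian intensity noise.  The analytic
displacement field is stored alongside the frames so every downstream
stage can be validated against exact ground truth.

The field-potential generator emulates a multielectrode-array recording of
a spontaneously beating well: a sharp biphasic depolarisation spike per
beat followed by a slower repolarisation wave at a controllable delay
(the field potential duration, FPD), with controllable beat period,
amplitude, period jitter and alternans.

All generators are pure functions of their spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ParameterError
from .flow import ImageSequence, TileGrid
from .fpmetrics import FieldPotentialTrace

__all__ = [
    "ContractionCenter",
    "SceneSpec",
    "FPSpec",
    "Video",
    "VideoGroundTruth",
    "FPGroundTruth",
    "generate_texture",
    "waveform_value",
    "displacement_at",
    "render_frame",
    "generate_video",
    "generate_field_potential",
]


@dataclass(frozen=True)
class ContractionCenter:
    """A Gaussian contractile center pulling tissue radially inward.

    ``amplitude`` is the peak displacement scale in pixels and ``radius``
    the Gaussian spatial extent (sigma) in pixels.
    """

    position: tuple[float, float]  # (row, col), pixels
    amplitude: float = 4.0  # pixels
    radius: float = 40.0  # pixels

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("contraction amplitude must be >= 0")
        if self.radius <= 0:
            raise ParameterError("contraction radius must be > 0")


def _default_centers(image_size: tuple[int, int]) -> tuple[ContractionCenter, ...]:
    H, W = image_size
    return (
        ContractionCenter(
            position=((H - 1) / 2.0, (W - 1) / 2.0),
            amplitude=4.0,
            radius=min(H, W) / 3.0,
        ),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic beating-monolayer recording.

    Defaults describe a 128x128 px field of view at 30 frames/s for 20 s
    with a single centered contractile focus beating at 1 Hz — a desk-scale
    stand-in for a videomicroscopy recording of a beating culture.
    """

    image_size: tuple[int, int] = (128, 128)  # (H, W) pixels
    texture_seed: int = 0
    texture_granularity: float = 4.0  # pixels (texture correlation length)
    centers: tuple[ContractionCenter, ...] | None = None  # default: one
    # center in the middle of the image (amplitude 4 px, radius min(H,W)/3)
    beat_frequency: float = 1.0  # Hz
    waveform: str = "sine"  # "sine" | "half_wave_pulse"
    duty_fraction: float = 0.3  # pulse width / period, for half_wave_pulse
    noise_sigma: float = 0.0  # intensity units (texture range is [0, 1])
    frame_rate: float = 30.0  # Hz
    duration: float = 20.0  # seconds

    def __post_init__(self) -> None:
        if self.centers is None:
            object.__setattr__(self, "centers", _default_centers(self.image_size))
        else:
            object.__setattr__(self, "centers", tuple(self.centers))
        H, W = self.image_size
        if H < 1 or W < 1:
            raise ParameterError("image_size must be positive")
        if self.texture_granularity < 1:
            raise ParameterError("texture_granularity must be >= 1 pixel")
        if self.beat_frequency <= 0:
            raise ParameterError("beat_frequency must be > 0")
        if self.frame_rate <= 2 * self.beat_frequency:
            raise ParameterError(
                "frame_rate must exceed twice the beat frequency (Nyquist margin)"
            )
        if not 0 < self.duty_fraction <= 1:
            raise ParameterError("duty_fraction must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.waveform not in ("sine", "half_wave_pulse"):
            raise ParameterError(f"unknown waveform {self.waveform!r}")
        for c in self.centers:
            r, col = c.position
            if not (0 <= r < H and 0 <= col < W):
                raise ParameterError("all contraction centers must lie within the image")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration * self.frame_rate))


@dataclass(frozen=True)
class FPSpec:
    """Parameters of a synthetic MEA field-potential trace.

    Defaults mirror a typical hiPSC-CM well: ~1 s beat period, FPD around
    0.35 s, and a sampling rate comfortably above 1 kHz.
    """

    sampling_rate: float = 5000.0  # Hz
    duration: float = 30.0  # s
    beat_period: float = 1.0  # s
    period_jitter_sd: float = 0.0  # s
    alternans_delta: float = 0.0  # s, alternating +/- offset on intervals
    spike_amplitude: float = 100.0  # voltage units, peak-to-trough
    fpd: float = 0.35  # s, spike-to-repolarisation-peak delay
    noise_sd: float = 0.0  # voltage units
    seed: int = 0
    # shape parameters of the waveform (not part of the metric contract)
    spike_width: float = 0.0015  # s, sigma of the depolarisation peak
    trough_width: float = 0.003  # s, sigma of the following trough
    trough_delay: float = 0.01  # s, peak-to-trough separation
    repol_fraction: float = 0.15  # repolarisation amplitude / spike amplitude
    repol_width: float = 0.025  # s, sigma of the repolarisation bump

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000:
            raise ParameterError("sampling_rate must be >= 1000 Hz")
        if not self.beat_period > self.fpd > 0:
            raise ParameterError("must have beat_period > fpd > 0")
        if self.alternans_delta >= self.beat_period / 2:
            raise ParameterError("alternans_delta must be < beat_period / 2")
        if self.period_jitter_sd < 0 or self.noise_sd < 0:
            raise ParameterError("jitter and noise standard deviations must be >= 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.spike_amplitude < 0 or self.repol_fraction < 0:
            raise ParameterError("amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# video scene


def generate_texture(spec: SceneSpec) -> np.ndarray:
    """Random monolayer-like texture: low-pass-filtered seeded white noise.

    The Gaussian blur sigma equals ``texture_granularity``, so the spatial
    autocorrelation length of the image scales with it.  Intensities are
    rescaled to [0, 1].  Deterministic given ``texture_seed``.
    """
    rng = np.random.default_rng(spec.texture_seed)
    noise = rng.standard_normal(spec.image_size)
    tex = gaussian_filter(noise, spec.texture_granularity, mode="reflect")
    lo, hi = tex.min(), tex.max()
    if hi - lo <= 0:
        raise ParameterError("degenerate texture (constant image)")
    return (tex - lo) / (hi - lo)


def waveform_value(spec: SceneSpec, t: np.ndarray | float) -> np.ndarray | float:
    """Contraction drive b(t) in [0, 1]; b(0) = 0 for both waveforms."""
    phase = np.mod(np.asarray(t, dtype=np.float64) * spec.beat_frequency, 1.0)
    if spec.waveform == "sine":
        b = np.sin(np.pi * phase) ** 2
    else:  # half_wave_pulse: clipped raised-cosine pulse of width duty*period
        b = np.where(
            phase < spec.duty_fraction,
            np.sin(np.pi * phase / spec.duty_fraction) ** 2,
            0.0,
        )
    return float(b) if np.isscalar(t) else b


def displacement_at(
    spec: SceneSpec, t: float, positions: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Analytic displacement d(t, x) at pixel positions ``(..., 2)``.

    Each center contributes ``-A * b(t) * (x - c)/sigma * exp(-|x-c|^2 /
    (2 sigma^2))``: zero at the center itself, radially inward elsewhere
    while the waveform is active.
    """
    x = np.asarray(positions, dtype=np.float64)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    b = float(waveform_value(spec, t))
    d = np.zeros_like(x)
    if b != 0.0:
        for c in spec.centers:
            rel = x - np.asarray(c.position)
            r2 = np.sum(rel * rel, axis=-1, keepdims=True)
            d -= (
                c.amplitude
                * b
                * rel
                / c.radius
                * np.exp(-r2 / (2.0 * c.radius**2))
            )
    return d[0] if squeeze else d


def analytic_convergence(
    spec: SceneSpec, t: float, positions: np.ndarray
) -> np.ndarray:
    """Closed-form convergence (negative divergence) of the analytic field.

    For one center, ``-div d = A*b/sigma * (2 - r^2/sigma^2) *
    exp(-r^2/(2 sigma^2))``, which tends to ``2*A*b/sigma`` at the center.
    """
    x = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    b = float(waveform_value(spec, t))
    out = np.zeros(x.shape[0])
    for c in spec.centers:
        rel = x - np.asarray(c.position)
        r2 = np.sum(rel * rel, axis=-1)
        s2 = c.radius**2
        out += c.amplitude * b / c.radius * (2.0 - r2 / s2) * np.exp(-r2 / (2.0 * s2))
    return out


def _frame_noise_rng(spec: SceneSpec, frame_index: int) -> np.random.Generator:
    # independent, reproducible stream per frame
    return np.random.default_rng([spec.texture_seed, 7919, frame_index])


def render_frame(
    spec: SceneSpec,
    t: float,
    texture: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame: texture warped by the analytic field, plus noise.

    Backward mapping: each output pixel samples the texture at
    ``x - d(t, x)`` with bilinear interpolation, so the stored analytic
    field is the *sampling* displacement.  With zero noise and b(t) = 0 the
    frame equals the texture bit-for-bit.
    """
    tex = generate_texture(spec) if texture is None else texture
    H, W = tex.shape
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pos = np.stack([rows, cols], axis=-1).reshape(-1, 2).astype(np.float64)
    d = displacement_at(spec, t, pos).reshape(H, W, 2)
    if np.abs(d).max() >= min(H, W):
        raise ParameterError("displacement magnitude exceeds the image size")
    frame = map_coordinates(
        tex,
        [rows - d[..., 0], cols - d[..., 1]],
        order=1,
        mode="reflect",
    )
    if spec.noise_sigma > 0:
        k = int(round(t * spec.frame_rate))
        frame = frame + _frame_noise_rng(spec, k).normal(0.0, spec.noise_sigma, frame.shape)
    return frame


@dataclass
class VideoGroundTruth:
    """Analytic displacement record accompanying a generated video."""

    grid: TileGrid
    times: np.ndarray  # (T,)
    fields: np.ndarray  # (T, n, 2) analytic d(t, x) at grid centers
    waveform: np.ndarray  # (T,) b(t)
    spec: SceneSpec

    def beat_pattern(self) -> np.ndarray:
        """Ground-truth D(t): spatial mean displacement magnitude."""
        return np.linalg.norm(self.fields, axis=2).mean(axis=1)


@dataclass
class Video:
    sequence: ImageSequence
    truth: VideoGroundTruth


def generate_video(
    spec: SceneSpec, grid_step: int = 16, grid_tile: int = 32, grid_margin: int = 0
) -> Video:
    """Generate a full synthetic recording plus its analytic ground truth.

    Frames are uniformly spaced at ``1/frame_rate``; the ground-truth field
    is stored on the default fine analysis grid (``grid_tile``-px tiles at
    ``grid_step``-px spacing) so estimated fields can be compared directly.
    """
    n = spec.n_frames
    if n < 3:
        raise ParameterError("spec yields fewer than 3 frames")
    tex = generate_texture(spec)
    times = np.arange(n) / spec.frame_rate
    frames = np.stack([render_frame(spec, t, texture=tex) for t in times])
    grid = TileGrid.regular(spec.image_size, grid_tile, grid_step, grid_margin)
    centers = grid.centers.astype(np.float64)
    fields = np.stack([displacement_at(spec, t, centers) for t in times])
    b = np.asarray(waveform_value(spec, times))
    truth = VideoGroundTruth(grid, times, fields, b, spec)
    return Video(ImageSequence(frames, 1.0 / spec.frame_rate), truth)


# ---------------------------------------------------------------------------
# field potential


@dataclass
class FPGroundTruth:
    spike_times: np.ndarray  # s
    intervals: np.ndarray  # s, successive inter-spike intervals
    fpd: float  # s
    spec: FPSpec


def generate_field_potential(spec: FPSpec) -> tuple[FieldPotentialTrace, FPGroundTruth]:
    """Synthesize an MEA-like field-potential trace with known beat structure.

    Spikes are placed at cumulative intervals ``beat_period + jitter -/+
    alternans_delta`` (alternating sign, minus first); each beat contributes
    a biphasic spike (dominant positive peak at the nominal spike time,
    smaller delayed trough; peak-to-trough height = ``spike_amplitude``) and
    a smooth repolarisation bump peaking ``fpd`` seconds after the spike.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs

    spike_times = []
    t_next = 0.3 * spec.beat_period  # lead-in before the first beat
    k = 0
    margin = spec.fpd + 4 * spec.repol_width
    while t_next < spec.duration - margin:
        spike_times.append(t_next)
        interval = (
            spec.beat_period
            + rng.normal(0.0, spec.period_jitter_sd)
            + spec.alternans_delta * (-1.0 if k % 2 == 0 else 1.0)
        )
        t_next = t_next + interval
        k += 1
    spike_times = np.asarray(spike_times)
    if spike_times.size < 1:
        raise ParameterError("trace too short to hold a single beat")
    intervals = np.diff(spike_times)
    if intervals.size and spec.fpd >= intervals.min():
        raise ParameterError("fpd must be shorter than the realized minimum interval")

    amp_pos = 0.7 * spec.spike_amplitude
    amp_neg = 0.3 * spec.spike_amplitude
    v = np.zeros(n)
    for ts in spike_times:
        # evaluate each component only on a local window for speed
        w0 = max(0, int((ts - 0.05) * fs))
        w1 = min(n, int((ts + 0.05) * fs) + 1)
        tw = t[w0:w1]
        v[w0:w1] += amp_pos * np.exp(-((tw - ts) ** 2) / (2 * spec.spike_width**2))
        v[w0:w1] -= amp_neg * np.exp(
            -((tw - ts - spec.trough_delay) ** 2) / (2 * spec.trough_width**2)
        )
        b0 = max(0, int((ts + spec.fpd - 5 * spec.repol_width) * fs))
        b1 = min(n, int((ts + spec.fpd + 5 * spec.repol_width) * fs) + 1)
        tb = t[b0:b1]
        v[b0:b1] += (
            spec.repol_fraction
            * spec.spike_amplitude
            * np.exp(-((tb - ts - spec.fpd) ** 2) / (2 * spec.repol_width**2))
        )
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, n)

    trace = FieldPotentialTrace(time=t, voltage=v, sampling_rate=fs)
    truth = FPGroundTruth(spike_times, intervals, spec.fpd, spec)
    return trace, truth
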