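"""Tests of reference-frame selection, beat patterns, and spectra."""

import numpy as np
import pytest

import beatflow as bf
from beatflow.beats import BeatTrace, MotionTrace
from beatflow.errors import InputError
from beatflow.flow import DisplacementField, TileGrid


def make_trace(values, rate=30.0):
    values = np.asarray(values, float)
    return BeatTrace(values=values, times=np.arange(values.size) / rate, reference=0)


def make_fields(vector_sets, valid_sets=None, reference=0):
    grid = TileGrid.regular((128, 128), 32, 16)
    out = []
    for t, vecs in enumerate(vector_sets):
        n = len(grid)
        vectors = np.zeros((n, 2))
        valid = np.ones(n, bool)
        if len(vecs):
            vectors[: len(vecs)] = vecs
        if valid_sets is not None:
            valid[:] = False
            valid[: len(valid_sets[t])] = valid_sets[t]
        out.append(
            DisplacementField(grid, vectors, np.zeros(n), valid, "fine", t, reference)
        )
    return out


class TestFrameMotion:
    def test_constant_sequence(self):
        img = np.random.default_rng(0).random((128, 128))
        seq = bf.ImageSequence(np.stack([img] * 4), 1 / 30)
        motion = bf.frame_motion(seq)
        assert np.all(motion.values == 0)
        assert motion.t_star == 0

    def test_argmin_lies_in_rest_interval(self):
        spec = bf.SceneSpec(
            waveform="half_wave_pulse",
            duty_fraction=0.3,
            duration=2.0,
            beat_frequency=1.0,
            texture_seed=4,
        )
        video = bf.generate_video(spec)
        motion = bf.frame_motion(video.sequence)
        # ground-truth rest mask: waveform inactive at the chosen frame
        assert video.truth.waveform[motion.t_star] == 0.0

    def test_pairwise_locality_under_frame_swap(self):
        spec = bf.SceneSpec(duration=1.0, frame_rate=12.0, beat_frequency=1.5)
        frames = bf.generate_video(spec).sequence.frames.copy()
        base = bf.frame_motion(bf.ImageSequence(frames, 1 / 12)).values
        swapped = frames.copy()
        swapped[[5, 6]] = swapped[[6, 5]]
        vs = bf.frame_motion(bf.ImageSequence(swapped, 1 / 12)).values
        # V(t) for pairs not touching the swapped frames is unchanged
        untouched = [t for t in range(len(frames) - 1) if t not in (4, 5, 6)]
        assert np.allclose(vs[untouched], base[untouched])


class TestSelectReference:
    def test_earliest_minimum_tie_break(self):
        motion = MotionTrace(values=np.array([0.5, 0.1, 0.1, 0.7]), t_star=0)
        assert bf.select_reference(motion) == 1

    def test_strictly_decreasing(self):
        motion = MotionTrace(values=np.array([3.0, 2.0, 1.0, 0.5]), t_star=0)
        assert bf.select_reference(motion) == 3


class TestBeatPattern:
    def test_all_zero_fields(self):
        fields = make_fields([[], [], []])
        trace = bf.beat_pattern(fields, 1 / 30)
        assert np.all(trace.values == 0)

    def test_single_vector_norm(self):
        grid = TileGrid.regular((128, 128), 32, 16)
        n = len(grid)
        vectors = np.zeros((n, 2))
        vectors[0] = (3, 4)
        valid = np.zeros(n, bool)
        valid[0] = True
        f = DisplacementField(grid, vectors, np.zeros(n), valid, "fine", 0, 0)
        trace = bf.beat_pattern([f], 1 / 30)
        assert trace.values[0] == 5.0

    def test_mean_of_unit_norms(self):
        grid = TileGrid.regular((128, 128), 32, 16)
        n = len(grid)
        vectors = np.zeros((n, 2))
        vectors[:4] = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        valid = np.zeros(n, bool)
        valid[:4] = True
        f = DisplacementField(grid, vectors, np.zeros(n), valid, "fine", 0, 0)
        assert bf.beat_pattern([f], 1 / 30).values[0] == 1.0

    def test_no_valid_centers_flagged_missing(self):
        grid = TileGrid.regular((128, 128), 32, 16)
        n = len(grid)
        f = DisplacementField(
            grid, np.zeros((n, 2)), np.zeros(n), np.zeros(n, bool), "fine", 0, 0
        )
        assert np.isnan(bf.beat_pattern([f], 1 / 30).values[0])

    def test_zero_at_reference_frame(self, video15, flow15):
        motion, fields = flow15
        trace = bf.beat_pattern(fields, video15.sequence.frame_interval)
        assert trace.values[motion.t_star] == 0.0


class TestPowerSpectrum:
    def test_pure_sine_single_peak(self):
        t = np.arange(900) / 30.0
        trace = make_trace(np.sin(2 * np.pi * 1.0 * t))
        spec = bf.power_spectrum(trace)
        k = int(np.argmax(spec.power))
        assert np.isclose(spec.frequencies[k], 1.0)
        others = np.delete(spec.power, k)
        assert others.max() <= 1e-6 * spec.power[k]

    def test_constant_trace_no_power(self):
        spec = bf.power_spectrum(make_trace(np.full(64, 3.7)))
        assert np.all(spec.power == 0)

    def test_harmonics_match_fourier_series_oracle(self):
        # half-wave pulse train at 1 Hz, duty 0.3: compare DFT power ratios
        # at 1, 2, 3 Hz against numerically integrated Fourier coefficients
        scene = bf.SceneSpec(waveform="half_wave_pulse", duty_fraction=0.3)
        from beatflow.synthetic import waveform_value

        rate, dur = 30.0, 30.0
        t = np.arange(int(rate * dur)) / rate
        b = np.asarray(waveform_value(scene, t))
        spec = bf.power_spectrum(make_trace(b, rate))

        # oracle: c_k = (1/T) * integral b(t) exp(-2 pi i k t) dt on a dense grid
        td = np.linspace(0.0, 1.0, 20001)
        bd = np.asarray(waveform_value(scene, td))
        coeffs = [
            np.trapezoid(bd * np.exp(-2j * np.pi * k * td), td) for k in (1, 2, 3)
        ]
        powers = []
        for k in (1, 2, 3):
            bin_k = int(round(k / spec.bin_width))
            powers.append(spec.power[bin_k])
        assert all(p > 0 for p in powers)
        expected_ratio21 = abs(coeffs[1]) ** 2 / abs(coeffs[0]) ** 2
        expected_ratio31 = abs(coeffs[2]) ** 2 / abs(coeffs[0]) ** 2
        assert np.isclose(powers[1] / powers[0], expected_ratio21, rtol=0.05)
        assert np.isclose(powers[2] / powers[0], expected_ratio31, rtol=0.05)

    def test_parseval_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.random(rng.integers(16, 200))
            spec = bf.power_spectrum(make_trace(x))
            var = np.var(x)  # population variance of the mean-subtracted trace
            assert np.isclose(spec.power.sum(), x.size * var, rtol=1e-9, atol=1e-12)

    def test_nonuniform_times_rejected(self):
        trace = make_trace(np.sin(np.arange(32)))
        trace.times = trace.times**1.01
        with pytest.raises(InputError):
            bf.power_spectrum(trace)


class TestDominantFrequency:
    def test_sine_fundamental(self):
        t = np.arange(900) / 30.0
        spec = bf.power_spectrum(make_trace(np.sin(2 * np.pi * 1.0 * t)))
        assert bf.dominant_frequency(spec) == 1.0
        assert np.allclose(spec.harmonic_frequencies[:3], [1.0, 2.0, 3.0])

    def test_end_to_end_recovery(self, video15, flow15):
        motion, fields = flow15
        trace = bf.beat_pattern(fields, video15.sequence.frame_interval)
        spec = bf.power_spectrum(trace)
        f = bf.dominant_frequency(spec)
        assert abs(f - 1.5) <= spec.bin_width

    def test_empty_band_rejected(self):
        spec = bf.power_spectrum(make_trace(np.sin(np.arange(32))))
        with pytest.raises(InputError):
            bf.dominant_frequency(spec, min_freq=1e6)

    def test_amplitude_monotonicity(self, video15, flow15):
        # doubling contraction amplitudes must not decrease max D(t)
        motion, fields = flow15
        base = bf.beat_pattern(fields, video15.sequence.frame_interval)
        spec0 = video15.truth.spec
        doubled = bf.SceneSpec(
            beat_frequency=spec0.beat_frequency,
            duration=2.0,
            texture_seed=spec0.texture_seed,
            centers=tuple(
                bf.ContractionCenter(c.position, 2 * c.amplitude, c.radius)
                for c in spec0.centers
            ),
        )
        video2 = bf.generate_video(doubled)
        m2 = bf.frame_motion(video2.sequence)
        f2 = bf.compute_flow(video2.sequence, m2.t_star)
        hi = bf.beat_pattern(f2, video2.sequence.frame_interval)
        assert np.nanmax(hi.values) >= np.nanmax(base.values)
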