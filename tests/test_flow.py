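"""Tests of tile matching, the two-stage flow pipeline, and TPS smoothing."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

import beatflow as bf
from beatflow.errors import FitError, InputError
from beatflow.flow import SmoothedField, ThinPlateSpline, TileGrid

from conftest import shifted_pair


def brute_force_match(tile, image, center, radius):
    """Independent exhaustive-search oracle with the documented tie-break:
    smallest Euclidean distance, then smallest |shift|, then (drow, dcol)."""
    T = tile.shape[0]
    half = T // 2
    H, W = image.shape
    best = None
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            r0 = center[0] - half + dy
            c0 = center[1] - half + dx
            if r0 < 0 or c0 < 0 or r0 + T > H or c0 + T > W:
                continue
            ssd = float(np.sum((image[r0 : r0 + T, c0 : c0 + T] - tile) ** 2))
            key = (ssd, dy * dy + dx * dx, dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx))
    return best[1], best[0][0]


class TestMatchTile:
    def test_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        m = bf.match_tile(img[20:36, 20:36], img, (28, 28), 5)
        assert tuple(m.shift) == (0, 0) and m.score == 0.0 and m.valid

    def test_constructed_shift(self):
        ref, mov = shifted_pair(2, shape=(64, 64), shift=(3, -2), pad=8)
        tile = ref[24:40, 24:40]  # interior 16-px tile centered at (32, 32)
        m = bf.match_tile(tile, mov, (32, 32), 4)
        assert tuple(m.shift) == (3, -2)
        assert m.score < 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_toy_images(self, seed):
        # integer intensities make the sums exact, so tie-breaks are exercised
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 4, (9, 9)).astype(float)
        other = rng.integers(0, 4, (9, 9)).astype(float)
        tile = img[3:6, 3:6]
        m = bf.match_tile(tile, other, (4, 4), 2, engine="direct")
        shift, score = brute_force_match(tile, other, (4, 4), 2)
        assert tuple(m.shift) == shift
        assert np.isclose(m.score, np.sqrt(score))

    def test_border_tile_all_candidates_invalid(self):
        img = np.random.default_rng(0).random((16, 16))
        m = bf.match_tile(img[:8, :8], img, (4, 4), 30)
        # every candidate window of a huge search leaves the image edge at
        # some shifts but (0,0) remains valid here; use an impossible center
        m2 = bf.match_tile(img[:8, :8], np.zeros((6, 6)), (3, 3), 1)
        assert not m2.valid and np.isnan(m2.score)
        assert m.valid


class TestCoarseField:
    def test_zero_for_identical_frames(self):
        img = np.random.default_rng(1).random((160, 160))
        f = bf.coarse_field(img, img)
        assert np.all(f.vectors == 0) and np.all(f.valid)
        assert np.all(f.scores == 0)

    def test_uniform_translation(self):
        ref, mov = shifted_pair(3, shape=(192, 192), shift=(5, 0))
        f = bf.coarse_field(ref, mov, margin=5)
        assert np.all(f.vectors == [5, 0])

    def test_image_smaller_than_tile_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(InputError):
            bf.coarse_field(img, img, tile_size=64)

    def test_correlates_with_synthetic_ground_truth(self):
        spec = bf.SceneSpec(texture_seed=11)
        tex = bf.generate_texture(spec)
        peak = bf.render_frame(spec, 0.5, texture=tex)  # peak contraction
        f = bf.coarse_field(tex, peak)
        truth = bf.displacement_at(spec, 0.5, f.grid.centers.astype(float))
        est, tru = f.vectors[f.valid].ravel(), truth[f.valid].ravel()
        cosine = est @ tru / (np.linalg.norm(est) * np.linalg.norm(tru))
        assert cosine > 0.9


class TestThinPlateSpline:
    def _noisy_grid(self, rng, n=12, spacing=16.0):
        xs = np.arange(n) * spacing
        pts = np.stack(np.meshgrid(xs, xs, indexing="ij"), -1).reshape(-1, 2)
        return pts

    def test_interpolates_exactly_at_zero_smoothing(self, rng):
        pts = rng.random((25, 2)) * 100
        vals = rng.random((25, 2))
        grid = TileGrid.regular((128, 128), 32, 16)
        fld = bf.DisplacementField(
            grid=grid,
            vectors=rng.random((len(grid), 2)),
            scores=np.zeros(len(grid)),
            valid=np.ones(len(grid), bool),
            level="coarse",
        )
        sm = bf.tps_smooth(fld, regularization=0.0)
        assert np.allclose(sm.evaluate(grid.centers.astype(float)), fld.vectors, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 100.0])
    def test_reproduces_affine_fields_for_any_smoothing(self, lam, rng):
        grid = TileGrid.regular((160, 160), 32, 16)
        M = np.array([[0.01, -0.02], [0.03, 0.015]])
        b = np.array([1.5, -0.5])
        centers = grid.centers.astype(float)
        vectors = centers @ M.T + b
        fld = bf.DisplacementField(
            grid, vectors, np.zeros(len(grid)), np.ones(len(grid), bool), "coarse"
        )
        sm = bf.tps_smooth(fld, regularization=lam)
        query = rng.random((40, 2)) * 159
        assert np.allclose(sm.evaluate(query), query @ M.T + b, atol=1e-7)

    def test_smoothing_reduces_noise_on_smooth_field(self):
        rng = np.random.default_rng(7)
        pts = self._noisy_grid(rng)
        clean = np.stack(
            [np.sin(2 * np.pi * pts[:, 0] / 120.0), np.cos(2 * np.pi * pts[:, 1] / 120.0)],
            axis=1,
        )
        noisy = clean + rng.normal(0.0, 0.5, clean.shape)
        spline = ThinPlateSpline(pts, noisy, smoothing=1.0)
        fitted = spline(pts)
        rms_fit = np.sqrt(np.mean((fitted - clean) ** 2))
        rms_noise = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rms_fit < rms_noise

    def test_agrees_with_scipy_rbf_interpolator(self, rng):
        # independent cross-check of the interpolation path
        pts = rng.random((30, 2)) * 100
        vals = rng.random(30)
        ours = ThinPlateSpline(pts, vals, smoothing=0.0)
        theirs = RBFInterpolator(pts, vals, kernel="thin_plate_spline", degree=1)
        query = rng.random((20, 2)) * 100
        assert np.allclose(ours(query), theirs(query), atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5.0), np.arange(5.0)], axis=1)
        with pytest.raises(FitError):
            ThinPlateSpline(pts, np.ones(5), 0.0)


def _constant_smoothed(grid, vector):
    const = np.asarray(vector, float)
    return SmoothedField(
        grid=grid,
        vectors=np.tile(const, (len(grid), 1)),
        scores=np.zeros(len(grid)),
        valid=np.ones(len(grid), bool),
        level="smoothed",
        evaluator=lambda q: np.tile(const, (np.atleast_2d(q).shape[0], 1)),
    )


class TestFineField:
    def test_zero_for_identical_frames(self):
        img = np.random.default_rng(2).random((128, 128))
        grid = TileGrid.regular(img.shape, 32, 16)
        f = bf.fine_field(img, img, _constant_smoothed(grid, (0, 0)))
        assert np.all(f.vectors == 0) and np.all(f.valid)

    def test_prediction_composition_beyond_radius(self):
        # true shift (7,0) exceeds the 4-px fine radius, but with a correct
        # coarse prediction the residual is zero
        ref, mov = shifted_pair(5, shape=(160, 160), shift=(7, 0))
        grid = TileGrid.regular(ref.shape, 32, 16, margin=7)
        f = bf.fine_field(ref, mov, _constant_smoothed(grid, (7, 0)), grid=grid)
        assert np.all(f.vectors == [7, 0])

    def test_two_stage_equals_single_stage_exhaustive(self):
        ref, mov = shifted_pair(6, shape=(192, 192), shift=(2, 1))
        c = bf.coarse_field(ref, mov, margin=2)
        sm = bf.tps_smooth(c, regularization=0.0)
        fine = bf.fine_field(ref, mov, sm, margin=2)
        grid = TileGrid.regular(ref.shape, 32, 16, margin=2)
        single = bf.coarse_field(ref, mov, tile_size=32, step=16, search_radius=10, margin=2)
        assert np.array_equal(fine.vectors, single.vectors)
        assert np.array_equal(fine.valid, single.valid)

    def test_refinement_locality(self):
        # |fine - rounded prediction| <= fine_radius per component, always
        rng = np.random.default_rng(8)
        ref = rng.random((128, 128))
        mov = rng.random((128, 128))  # unrelated images: worst case
        grid = TileGrid.regular(ref.shape, 32, 16)
        pred = (3, -2)
        f = bf.fine_field(ref, mov, _constant_smoothed(grid, pred), fine_radius=4)
        resid = f.vectors[f.valid] - np.asarray(pred)
        assert np.all(np.abs(resid) <= 4)


class TestComputeFlow:
    def test_constant_sequence_gives_zero_fields(self):
        img = np.random.default_rng(3).random((128, 128))
        seq = bf.ImageSequence(np.stack([img, img, img]), 1 / 30)
        fields = bf.compute_flow(seq, 0)
        for f in fields:
            assert np.all(f.vectors == 0) and np.all(f.valid)

    def test_accuracy_against_ground_truth(self, video15, flow15):
        motion, fields = flow15
        est = np.stack([f.vectors for f in fields])
        err = np.linalg.norm(est - video15.truth.fields, axis=2).mean()
        assert err <= 0.75

    def test_reference_field_identically_zero(self, flow15):
        motion, fields = flow15
        ref_field = fields[motion.t_star]
        assert np.all(ref_field.vectors == 0)

    def test_frame_order_reversal(self):
        spec = bf.SceneSpec(duration=1.0, image_size=(96, 96), frame_rate=12.0, beat_frequency=1.5)
        video = bf.generate_video(spec)
        seq = video.sequence
        fwd = bf.compute_flow(seq, 0, regularization=1.0)
        rev_seq = bf.ImageSequence(seq.frames[::-1].copy(), seq.frame_interval)
        rev = bf.compute_flow(rev_seq, len(seq) - 1, regularization=1.0)
        for a, b in zip(fwd, rev[::-1]):
            assert np.array_equal(a.vectors, b.vectors)

    def test_bit_identical_reruns(self):
        spec = bf.SceneSpec(duration=1.0, image_size=(96, 96), frame_rate=12.0, beat_frequency=1.5)
        seq = bf.generate_video(spec).sequence
        a = bf.compute_flow(seq, 0)
        b = bf.compute_flow(seq, 0)
        for x, y in zip(a, b):
            assert np.array_equal(x.vectors, y.vectors)
            assert np.array_equal(x.scores, y.scores)

    def test_uniform_shift_oracle_multiple_seeds(self):
        # two-stage pipeline == exhaustive fine-grid search for uniform
        # integer shifts within the coarse radius, across random textures
        rng = np.random.default_rng(99)
        for seed in range(5):
            shift = tuple(rng.integers(-6, 7, 2))
            ref, mov = shifted_pair(seed, shape=(160, 160), shift=shift)
            margin = int(np.abs(shift).max())
            c = bf.coarse_field(ref, mov, margin=margin)
            fine = bf.fine_field(ref, mov, bf.tps_smooth(c, 0.0), margin=margin)
            single = bf.coarse_field(
                ref, mov, tile_size=32, step=16, search_radius=10, margin=margin
            )
            assert np.array_equal(fine.vectors, single.vectors), shift
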