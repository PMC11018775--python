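import numpy as np
import pytest
from scipy import ndimage

from condquant.core import ImageStack
from condquant.imgprep import (
    DriftTrace,
    bandpass,
    bleach_correct,
    drift_correct,
    estimate_flat_field,
    flat_field_correct,
    kymograph,
    register_translation,
    subtract_background_rolling_ball,
    walking_average,
)
from condquant.synthgen import (
    NoiseConfig,
    add_gaussian_2d,
    make_bead_pair,
    make_flatfield,
)


class TestFlatField:
    def test_uniform_stack_gives_ones(self):
        stack = np.full((25, 40, 40), 7.0)
        flat = estimate_flat_field(stack)
        assert np.allclose(flat, 1.0, atol=1e-9)

    def test_recovers_multiplicative_gradient(self):
        rng = np.random.default_rng(0)
        g = make_flatfield((64, 64), 0.4)
        frames = np.stack([(100 + rng.poisson(50, (64, 64))) * g
                           for _ in range(60)])
        est = estimate_flat_field(frames)
        # proportional to g within 2%
        ratio = est / (g / g.mean())
        assert np.abs(ratio - 1).max() < 0.02

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        g = make_flatfield((48, 48), 0.3)
        frames = np.stack([150.0 * g for _ in range(30)])
        flat = estimate_flat_field(frames)
        corrected = flat_field_correct(frames, flat)
        flat2 = estimate_flat_field(corrected)
        assert np.abs(flat2 - 1).max() < 0.02

    def test_too_few_frames_errors(self):
        with pytest.raises(ValueError):
            estimate_flat_field(np.ones((5, 16, 16)))

    def test_correct_identity_field(self):
        img = np.random.default_rng(2).random((16, 16))
        assert np.allclose(flat_field_correct(img, np.ones((16, 16))), img)

    def test_correct_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            flat_field_correct(np.ones((8, 8)), np.ones((9, 9)))

    def test_correct_zero_field_errors(self):
        flat = np.ones((8, 8))
        flat[3, 3] = 0
        with pytest.raises(ValueError):
            flat_field_correct(np.ones((8, 8)), flat)

    def test_gradient_roundtrip_cv(self):
        # invariant: correct(estimate) on gradient-corrupted constant < 2% CV
        g = make_flatfield((64, 64), 0.5)
        frames = np.stack([200.0 * g] * 25)
        corrected = flat_field_correct(frames, estimate_flat_field(frames))
        cv = corrected.std() / corrected.mean()
        assert cv < 0.02


class TestRollingBall:
    def test_constant_image_zeroed(self):
        out = subtract_background_rolling_ball(np.full((32, 32), 9.0), 5)
        assert np.allclose(out, 0.0)

    def test_spot_amplitude_preserved(self):
        img = np.full((64, 64), 50.0)
        add_gaussian_2d(img, 32.0, 32.0, 100.0, 1.5)
        out = subtract_background_rolling_ball(img, 15)
        assert out.max() == pytest.approx(100.0, rel=0.10)
        # offset removed far from the spot
        assert abs(out[5, 5]) < 1.0

    def test_bad_radius_errors(self):
        with pytest.raises(ValueError):
            subtract_background_rolling_ball(np.ones((16, 16)), 0)
        with pytest.raises(ValueError):
            subtract_background_rolling_ball(np.ones((16, 16)), 16)


class TestBandpass:
    def test_constant_gives_zero(self):
        assert np.allclose(bandpass(np.full((32, 32), 5.0), 1, 5), 0.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0, 10, (256, 256))
        out = bandpass(img, 1, 10, clip=False)
        assert img.var() / out.var() >= 5

    def test_spot_center_preserved(self):
        from condquant.puncta import detect_spots, localize_gaussian

        img = np.full((64, 64), 10.0)
        add_gaussian_2d(img, 30.6, 25.3, 200.0, 1.2)
        bp = bandpass(img, 1, 4, clip=False)
        spots = localize_gaussian(bp, [(31, 25)])
        assert spots[0].fit_ok
        assert abs(spots[0].y_px - 30.6) < 0.1
        assert abs(spots[0].x_px - 25.3) < 0.1

    def test_inverted_sigmas_error(self):
        with pytest.raises(ValueError):
            bandpass(np.ones((8, 8)), 5, 1)


class TestBleachCorrect:
    def test_exponential_decay_flattened(self):
        rng = np.random.default_rng(4)
        base = 100 + rng.random((32, 32)) * 20
        stack = np.stack([base * np.exp(-0.02 * t) for t in range(40)])
        out = bleach_correct(stack, "exponential")
        means = out.reshape(40, -1).mean(axis=1)
        assert np.abs(means / means[0] - 1).max() < 0.01

    def test_no_decay_nearly_unchanged(self):
        stack = np.stack([np.full((16, 16), 50.0)] * 10)
        out = bleach_correct(stack, "exponential")
        assert np.allclose(out, stack, rtol=0.01)

    def test_ratio_mode_exact(self):
        stack = np.stack([np.full((8, 8), v) for v in (10, 8, 6, 5, 4.0)])
        out = bleach_correct(stack, "ratio")
        means = out.reshape(5, -1).mean(axis=1)
        assert np.allclose(means, 10.0)

    def test_too_few_frames_errors(self):
        with pytest.raises(ValueError):
            bleach_correct(np.ones((3, 8, 8)))


class TestRegisterTranslation:
    def test_identical_images_zero_offset(self):
        a, _ = make_bead_pair(10, (0.0, 0.0), seed=5)
        offset, residuals, _ = register_translation(a, a)
        assert np.allclose(offset, 0.0, atol=1e-3)

    def test_recovers_generator_offset(self):
        noise = NoiseConfig(read_noise_sd=1.0, background_level=50.0)
        a, b = make_bead_pair(12, (1.5, -0.7), noise=noise, seed=6)
        offset, residuals, apply = register_translation(a, b)
        assert np.allclose(offset, (1.5, -0.7), atol=0.05)
        # applying the correction should re-align the bead field
        realigned = apply(b)
        off2, _, _ = register_translation(a, realigned)
        assert np.allclose(off2, 0.0, atol=0.1)

    def test_unmatched_fields_error(self):
        a, _ = make_bead_pair(5, seed=7)
        c, _ = make_bead_pair(5, seed=99)  # different bead positions
        with pytest.raises(ValueError):
            register_translation(a, c, match_radius_px=2.0)


class TestDriftCorrect:
    def _drifting_stack(self, v=(0.8, -0.5), n=8):
        rng = np.random.default_rng(8)
        base = np.zeros((96, 96))
        for _ in range(12):
            add_gaussian_2d(base, *rng.uniform(20, 76, 2), 300.0, 2.0)
        frames = [base]
        for t in range(1, n):
            frames.append(ndimage.shift(base, (v[0] * t, v[1] * t), order=1,
                                        mode="nearest"))
        return np.stack(frames), v

    def test_recovers_linear_drift(self):
        stack, v = self._drifting_stack()
        corrected, trace = drift_correct(stack)
        # correction shifts are the negated drift
        for t in range(1, len(trace)):
            assert np.allclose(-trace.shifts[t], (v[0] * t, v[1] * t), atol=0.1 * t + 0.1)

    def test_no_drift_near_zero(self):
        stack, _ = self._drifting_stack(v=(0.0, 0.0))
        _, trace = drift_correct(stack)
        assert np.abs(trace.shifts).max() < 0.05

    def test_single_frame_errors(self):
        with pytest.raises(ValueError):
            drift_correct(np.ones((1, 16, 16)))

    def test_corrected_matches_static(self):
        stack, _ = self._drifting_stack(n=5)
        corrected, _ = drift_correct(stack)
        inner = (slice(10, 86), slice(10, 86))
        for t in range(5):
            mad = np.abs(corrected[t][inner] - stack[0][inner]).mean()
            assert mad < 2.0

    def test_drifttrace_invariants(self):
        with pytest.raises(ValueError):
            DriftTrace(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestWalkingAverage:
    def test_k1_identity(self):
        stack = np.random.default_rng(9).random((6, 8, 8))
        assert np.array_equal(walking_average(stack, 1), stack)

    def test_constant_unchanged(self):
        stack = np.full((7, 8, 8), 3.0)
        assert np.allclose(walking_average(stack, 3), 3.0)

    def test_alternating_pattern_hand_computed(self):
        # frames 0,2,0,2,...; k=3 interior: mean is 4/3 at even, 2/3 at odd
        vals = [0.0, 2.0] * 4
        stack = np.stack([np.full((4, 4), v) for v in vals])
        out = walking_average(stack, 3)
        for t in range(1, 7):
            expected = (vals[t - 1] + vals[t] + vals[t + 1]) / 3
            assert np.allclose(out[t], expected)
        # truncated edges average over two frames
        assert np.allclose(out[0], (vals[0] + vals[1]) / 2)

    def test_even_k_errors(self):
        with pytest.raises(ValueError):
            walking_average(np.ones((5, 4, 4)), 2)


class TestKymograph:
    def test_static_spot_vertical_stripe(self):
        frame = np.zeros((32, 32))
        add_gaussian_2d(frame, 16.0, 16.0, 100.0, 1.5)
        movie = np.stack([frame] * 6)
        kymo = kymograph(movie, ((16.0, 4.0), (16.0, 28.0)))
        peak_cols = kymo.argmax(axis=1)
        assert len(set(peak_cols.tolist())) == 1

    def test_moving_spot_diagonal(self):
        frames = []
        for t in range(8):
            f = np.zeros((32, 48))
            add_gaussian_2d(f, 16.0, 8.0 + t, 100.0, 1.2)
            frames.append(f)
        kymo = kymograph(np.stack(frames), ((16.0, 0.0), (16.0, 47.0)))
        cols = kymo.argmax(axis=1)
        assert np.allclose(np.diff(cols), 1)

    def test_matches_interpolation_oracle(self):
        rng = np.random.default_rng(10)
        movie = rng.random((3, 24, 24))
        line = ((2.0, 3.0), (20.0, 17.0))
        kymo = kymograph(movie, line, n_samples=11)
        s = np.linspace(0, 1, 11)
        for t in range(3):
            for i, ss in enumerate(s):
                y = 2.0 + ss * 18.0
                x = 3.0 + ss * 14.0
                oracle = ndimage.map_coordinates(movie[t], [[y], [x]], order=1,
                                                 mode="nearest")[0]
                assert kymo[t, i] == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_line_errors(self):
        with pytest.raises(ValueError):
            kymograph(np.ones((3, 16, 16)), ((5.0, 5.0), (5.0, 5.2)))


class TestProvenance:
    def test_each_op_appends_once(self):
        stack = ImageStack(np.random.default_rng(11).random((6, 16, 16)) + 1,
                           "TYX", pixel_size_nm=110.0, frame_interval_s=0.1)
        out = walking_average(stack, 3)
        assert len(out.provenance) == len(stack.provenance) + 1
        out2 = bandpass(out, 1, 3)
        assert len(out2.provenance) == len(out.provenance) + 1
        out3 = bleach_correct(out2, "ratio")
        assert len(out3.provenance) == len(out2.provenance) + 1
        # shape and metadata preserved
        assert out3.pixels.shape == stack.pixels.shape
        assert out3.pixel_size_nm == stack.pixel_size_nm
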