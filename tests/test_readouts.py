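import numpy as np
import pytest

from condquant import synthgen
from condquant.readouts import (
    FRAPTrace,
    bin_by_expression,
    fit_half_life,
    frap_analyze,
    oppuro_cell_intensity,
    phansalkar_threshold,
    pla_count,
    reporter_normalize,
    segment_nuclei,
    spine_change,
    spine_volume,
    ttest_two_tailed,
)
from condquant.synthgen import (
    NoiseConfig,
    ReporterConfig,
    add_gaussian_2d,
    apply_noise,
    make_frap_trace,
    make_reporter_traces,
    make_spine_series,
)


class TestReporterNormalize:
    def test_constant_traces_endpoint_one(self):
        traces = np.full((4, 10), 37.0)
        norm, mean, sd, kept = reporter_normalize(np.arange(10), traces)
        assert mean == 1.0

    def test_noiseless_alpha_one_quarter(self):
        t, traces = make_reporter_traces(
            6, ReporterConfig(half_life_h=6.0, inhibition_alpha=1.0,
                              noise_sd=0.0), duration_h=12.0, seed=1)
        norm, mean, sd, kept = reporter_normalize(t, traces)
        assert mean == pytest.approx(0.25, abs=1e-9)

    def test_mixture_matches_closed_form(self):
        alphas = np.array([0.2, 0.5, 0.8])
        t, traces = make_reporter_traces(
            3, ReporterConfig(noise_sd=0.0), duration_h=12.0, seed=2,
            alphas=alphas)
        norm, mean, sd, kept = reporter_normalize(t, traces)
        expected = np.mean((1 - alphas) + alphas * 0.25)
        assert mean == pytest.approx(expected, abs=1e-9)

    def test_zero_initial_excluded(self):
        traces = np.array([[0.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        with pytest.warns(UserWarning):
            norm, mean, sd, kept = reporter_normalize(np.arange(3), traces)
        assert kept.tolist() == [1]

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            reporter_normalize(np.array([0]), np.ones((2, 1)))


class TestBinByExpression:
    def test_all_in_one_bin(self):
        df = bin_by_expression([50, 60, 70], [1.0, 0.9, 0.8])
        assert df.iloc[0]["n"] == 3
        assert df["n"].sum() == 3

    def test_edge_value_goes_to_upper_bin(self):
        df = bin_by_expression([100.0], [0.5])
        assert df.iloc[1]["n"] == 1
        assert df.iloc[0]["n"] == 0

    def test_out_of_range_excluded(self):
        df = bin_by_expression([450.0, 50.0], [0.1, 0.2])
        assert df.attrs["n_excluded"] == 1

    def test_monotone_generator_gives_monotone_bins(self):
        rng = np.random.default_rng(3)
        expr = rng.uniform(0, 400, 200)
        endpoint = 1.0 - expr / 500.0 + rng.normal(0, 0.01, 200)
        df = bin_by_expression(expr, endpoint)
        means = df["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_bad_edges_error(self):
        with pytest.raises(ValueError):
            bin_by_expression([1], [1], bin_edges=(0, 0, 10))


class TestFitHalfLife:
    def test_exact_six_hours(self):
        t = np.linspace(0, 24, 30)
        v = np.exp(-t * np.log(2) / 6.0)
        t_half, diag = fit_half_life(t, v)
        assert t_half == pytest.approx(6.0, rel=1e-6)

    def test_floor_aware_recovery(self):
        t = np.linspace(0, 24, 30)
        v = 0.9 * np.exp(-t * np.log(2) / 6.0) + 0.1
        t_half, diag = fit_half_life(t, v, with_floor=True)
        assert t_half == pytest.approx(6.0, rel=0.02)

    def test_rising_trace_errors(self):
        t = np.linspace(0, 10, 10)
        with pytest.raises(ValueError):
            fit_half_life(t, np.exp(t / 10))


class TestFrapAnalyze:
    def _trace(self, m, tau=20.0, noise=0.0, seed=0):
        t, v, pre, bleach = make_frap_trace(m, tau, noise_sd=noise, seed=seed,
                                            n_post=300)
        return FRAPTrace(t, v, pre, bleach)

    def test_full_recovery(self):
        res = frap_analyze(self._trace(1.0))
        assert res.mobile_fraction == pytest.approx(1.0, abs=0.01)

    def test_flat_post_bleach(self):
        res = frap_analyze(self._trace(0.0))
        assert res.mobile_fraction == pytest.approx(0.0, abs=0.01)

    def test_recovery_with_noise(self):
        res = frap_analyze(self._trace(0.6, noise=0.02, seed=3))
        assert res.mobile_fraction == pytest.approx(0.6, abs=0.05)
        assert res.tau_s == pytest.approx(20.0, rel=0.3)
        assert res.immobile_fraction == pytest.approx(1 - res.mobile_fraction)

    def test_no_bleach_errors(self):
        t = np.arange(20.0)
        v = np.ones(20)
        with pytest.raises(ValueError):
            frap_analyze(FRAPTrace(t, v, 5, 5))

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            FRAPTrace(np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                      pre_frames=2, bleach_index=1)


class TestSpineVolume:
    def test_blank_roi_zero(self):
        stack = np.zeros((2, 8, 20, 20))
        vols = spine_volume(stack, [(0, 8, 0, 20, 0, 20)])
        assert np.allclose(vols, 0.0)

    def test_sphere_volume_within_tolerance(self):
        stack, truth, rois = make_spine_series(
            3, [5, 6, 5], growth_factor=1.0, seed=4,
            noise=NoiseConfig(read_noise_sd=1.0, background_level=20.0))
        vols = spine_volume(stack.pixels, rois)
        for s in range(3):
            assert vols[s, 0] == pytest.approx(truth[s, 0], rel=0.15)

    def test_intensity_doubling_robust(self):
        stack, truth, rois = make_spine_series(
            1, [5], growth_factor=1.0, seed=5,
            noise=NoiseConfig(read_noise_sd=1.0, background_level=20.0))
        v1 = spine_volume(stack.pixels, rois)
        v2 = spine_volume(stack.pixels * 2.0, rois)
        assert np.abs(v2 / v1 - 1).max() < 0.05

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError):
            spine_volume(np.zeros((1, 4, 8, 8)), [(2, 2, 0, 8, 0, 8)])

    def test_phansalkar_surface_shape(self):
        img = np.random.default_rng(6).random((32, 32))
        thr = phansalkar_threshold(img)
        assert thr.shape == img.shape


class TestSpineChange:
    def test_constant_spine_trace_one(self):
        v = np.full((5, 8), 100.0)
        norm, mean, sem = spine_change(v)
        assert np.allclose(norm, 1.0)
        assert np.allclose(sem, 0.0)

    def test_growth_endpoint(self):
        v = np.concatenate([np.full((4, 3), 100.0), np.full((4, 3), 150.0)],
                           axis=1)
        norm, mean, sem = spine_change(v)
        assert mean[-1] == pytest.approx(1.5)

    def test_sem_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(80, 120, (12, 6))
        norm, mean, sem = spine_change(v)
        for j in range(6):
            direct = norm[:, j].std(ddof=1) / np.sqrt(norm.shape[0])
            assert sem[j] == pytest.approx(direct, abs=1e-12)

    def test_zero_baseline_excluded(self):
        v = np.vstack([np.zeros((1, 6)), np.full((3, 6), 10.0)])
        with pytest.warns(UserWarning):
            norm, mean, sem = spine_change(v)
        assert norm.shape[0] == 3


def _nuclei_image(centers, radius=10, shape=(96, 96)):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = 100.0
    return img


class TestOppuro:
    def test_uniform_opp_returns_uniform_level(self):
        nuclei = _nuclei_image([(48, 48)])
        opp = np.full((3, 96, 96), 42.0)
        out = oppuro_cell_intensity(opp, nuclei)
        assert len(out) == 1
        assert list(out.values())[0] == pytest.approx(42.0)

    def test_touching_nuclei_split(self):
        nuclei = _nuclei_image([(48, 38), (48, 56)], radius=10)
        labels = segment_nuclei(nuclei, smooth_sigma=1.5)
        assert labels.max() == 2

    def test_z_profile_max_selected(self):
        nuclei = _nuclei_image([(48, 48)])
        opp = np.zeros((6, 96, 96))
        for z, v in enumerate([10, 20, 30, 80, 30, 10]):
            opp[z] = v
        out = oppuro_cell_intensity(opp, nuclei)
        assert list(out.values())[0] == pytest.approx(80.0)

    def test_no_nuclei_empty(self):
        out = oppuro_cell_intensity(np.ones((2, 64, 64)), np.zeros((64, 64)))
        assert out == {}


class TestPlaCount:
    def test_blank_zero(self):
        masks = np.zeros((64, 64), int)
        masks[10:50, 10:50] = 1
        counts = pla_count(np.zeros((3, 64, 64)), masks)
        assert counts == {1: 0}

    def test_planted_spots_counted(self):
        rng = np.random.default_rng(8)
        n_spots = 15
        clean = np.zeros((128, 128))
        pts = []
        while len(pts) < n_spots:
            p = rng.uniform(15, 113, 2)
            if all(np.hypot(*(p - q)) > 10 for q in pts):
                pts.append(p)
                add_gaussian_2d(clean, p[0], p[1], 150.0, 1.2)
        noise = NoiseConfig(read_noise_sd=2.0, background_level=100.0)
        img = apply_noise(clean, noise, rng)
        masks = np.ones((128, 128), int)
        counts = pla_count(img[None], masks)
        assert counts[1] == n_spots

    def test_spot_assigned_to_containing_mask(self):
        clean = np.zeros((64, 64))
        add_gaussian_2d(clean, 20.0, 20.0, 200.0, 1.2)
        masks = np.zeros((64, 64), int)
        masks[:, :32] = 1
        masks[:, 32:] = 2
        counts = pla_count(clean[None] + 10, masks)
        assert counts[1] == 1
        assert counts[2] == 0


class TestTTest:
    def test_identical_samples(self):
        t, df, p = ttest_two_tailed([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_values(self):
        t, df, p = ttest_two_tailed([1.0, 2, 3], [2.0, 3, 4])
        assert t == pytest.approx(-1.225, abs=1e-3)
        assert df == 4

    def test_swap_flips_sign_same_p(self):
        t1, _, p1 = ttest_two_tailed([1.0, 2, 3], [2.0, 3, 5])
        t2, _, p2 = ttest_two_tailed([2.0, 3, 5], [1.0, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_constant_equal_samples_p_one(self):
        t, df, p = ttest_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_welch_option(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 10)
        t_s, df_s, _ = ttest_two_tailed(a, b, equal_var=True)
        t_w, df_w, _ = ttest_two_tailed(a, b, equal_var=False)
        assert df_w < df_s

    def test_small_samples_error(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [1.0, 2.0])

    def test_type_i_error_calibration_quick(self):
        # 2000 null draws: rejection rate ~ alpha
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, (2000, 10))
        b = rng.normal(0, 1, (2000, 10))
        from scipy import stats

        res = stats.ttest_ind(a, b, axis=1)
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.03 < rate < 0.07
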