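import numpy as np
import pytest

from dissolvis import structure, volio, wetting
from dissolvis.errors import FitError, ValidationError


def _vol(values, voxel=20.18):
    return volio.VoxelVolume(np.asarray(values, dtype=np.float32), voxel)


def _full_mask(shape):
    return volio.BinaryMask(np.ones(shape, dtype=bool))


class TestVoiHistogram:
    def test_constant_voi_single_bin(self):
        vol = _vol(np.full((4, 4, 4), 7.0))
        hist = wetting.voi_histogram(vol, _full_mask((4, 4, 4)), 64, (0.0, 10.0))
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.sum() == 64

    def test_counts_sum_to_voi_size(self, rng):
        vol = _vol(rng.normal(100, 20, size=(6, 6, 6)))
        mask = volio.BinaryMask(rng.random((6, 6, 6)) > 0.4)
        hist = wetting.voi_histogram(vol, mask, 32, (0.0, 200.0))
        assert hist.counts.sum() == mask.count

    def test_empty_mask_rejected(self):
        vol = _vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValidationError):
            wetting.voi_histogram(vol, volio.BinaryMask(np.zeros((2, 2, 2), bool)), 8)

    def test_mid_dissolution_histogram_is_bimodal(self, rng):
        # two overlapping gray modes, peaks separated by >= 3 bin widths
        gray = np.concatenate(
            [rng.normal(100, 5, 4000), rng.normal(150, 5, 3000)]
        ).astype(np.float32)
        vol = _vol(gray.reshape(10, 10, 70))
        hist = wetting.voi_histogram(vol, _full_mask(vol.shape), 256, (80.0, 220.0))
        assert wetting.count_histogram_modes(hist) == 2
        smooth_peaks = np.flatnonzero(
            (hist.counts >= np.roll(hist.counts, 1))
            & (hist.counts > np.roll(hist.counts, -1))
        )
        assert smooth_peaks.max() - smooth_peaks.min() >= 3


class TestFitGaussian:
    def test_recovers_sampled_normal(self, rng):
        draws = rng.normal(100.0, 5.0, size=10**6)
        counts, edges = np.histogram(draws, bins=256, range=(70, 130))
        comp = wetting.fit_gaussian(wetting.HistogramModel(edges, counts))
        assert comp.mean == pytest.approx(100.0, abs=0.2)
        assert comp.sd == pytest.approx(5.0, abs=0.2)
        assert comp.weight == pytest.approx(10**6, rel=0.02)

    def test_symmetric_histogram_centered(self):
        edges = np.linspace(0, 10, 11)
        counts = np.array([0, 0, 1, 5, 9, 9, 5, 1, 0, 0])
        comp = wetting.fit_gaussian(wetting.HistogramModel(edges, counts))
        assert comp.mean == pytest.approx(5.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        edges = np.linspace(0, 10, 11)
        counts = np.zeros(10)
        counts[3] = 100
        with pytest.raises(FitError):
            wetting.fit_gaussian(wetting.HistogramModel(edges, counts))


class TestGaussianIntersection:
    def test_equal_sd_equal_weight_is_midpoint(self):
        a = wetting.GaussianComponent(10.0, 2.0, 100.0)
        b = wetting.GaussianComponent(20.0, 2.0, 100.0)
        assert wetting.gaussian_intersection(a, b) == pytest.approx(15.0, abs=1e-12)

    def test_general_case_matches_grid_scan_oracle(self, rng):
        for _ in range(25):
            mu_a = rng.uniform(0, 50)
            mu_b = mu_a + rng.uniform(5, 60)
            a = wetting.GaussianComponent(mu_a, rng.uniform(1, 8), rng.uniform(10, 1e5))
            b = wetting.GaussianComponent(mu_b, rng.uniform(1, 8), rng.uniform(10, 1e5))
            try:
                x = wetting.gaussian_intersection(a, b)
            except ValidationError:
                continue  # no root between the means for this draw
            grid = np.linspace(a.mean, b.mean, 200_001)
            diff = a.density(grid) - b.density(grid)
            sign_change = np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))
            assert sign_change.size > 0
            oracle = grid[sign_change[0]]
            assert abs(x - oracle) <= 2 * (grid[1] - grid[0])

    def test_symmetric_under_component_swap(self):
        a = wetting.GaussianComponent(10.0, 2.0, 500.0)
        b = wetting.GaussianComponent(25.0, 4.0, 900.0)
        assert wetting.gaussian_intersection(a, b) == pytest.approx(
            wetting.gaussian_intersection(a, b)
        )
        with pytest.raises(ValidationError):
            wetting.gaussian_intersection(b, a)  # must be reordered by caller

    def test_identical_components_rejected(self):
        a = wetting.GaussianComponent(10.0, 2.0, 100.0)
        with pytest.raises(ValidationError):
            wetting.gaussian_intersection(a, a)


class TestThresholdClassify:
    def test_extreme_thresholds(self, rng):
        vol = _vol(rng.normal(100, 5, size=(5, 5, 5)))
        mask = _full_mask((5, 5, 5))
        assert wetting.threshold_classify(vol, mask, 1e9).count == 0
        assert wetting.threshold_classify(vol, mask, -1e9).count == mask.count

    def test_noise_free_phantom_classified_exactly(self, clean_spec, clean_series):
        series, truth = clean_series
        mid = series.volumes[1]  # partially wetted, no blur, no noise
        threshold = 0.5 * (clean_spec.mu_matrix + clean_spec.wet_matrix_gray)
        wet = wetting.threshold_classify(mid, truth.matrix_mask, threshold)
        frac = wet.count / truth.matrix_mask.count
        assert frac == pytest.approx(truth.wet_fraction_per_time[1], abs=1e-12)


class TestExtractFeatures:
    def test_small_geometries(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True  # solid 3x3x3 cube in background
        vol = _vol(np.zeros((5, 5, 5)))
        feats = wetting.extract_features(vol, volio.BinaryMask(mask))
        assert len(feats) == 27
        edt = {tuple(c): d for c, d in zip(feats.coords, feats.edt)}
        assert edt[(2, 2, 2)] == pytest.approx(2.0)  # cube center
        assert edt[(1, 1, 1)] == pytest.approx(1.0)  # face-adjacent corner voxel

    def test_matches_bruteforce_all_pairs(self, rng):
        mask = rng.random((10, 10, 10)) > 0.5
        vol = _vol(np.zeros((10, 10, 10)))
        feats = wetting.extract_features(vol, volio.BinaryMask(mask))
        bg = np.argwhere(~mask)
        for c, d in zip(feats.coords[::17], feats.edt[::17]):
            zyx = np.array([c[2], c[1], c[0]])
            brute = np.sqrt(((bg - zyx) ** 2).sum(axis=1).min())
            assert d == pytest.approx(brute, abs=1e-9)


def _feature_cloud(rng, n, gray_mu, gray_sd):
    coords = rng.integers(0, 30, size=(n, 3))
    return wetting.VoxelFeatures(
        coords=coords,
        gray=rng.normal(gray_mu, gray_sd, size=n),
        edt=rng.uniform(0, 5, size=n),
    )


class TestKnn:
    def test_separated_grays_give_zero_validation_error(self, rng):
        first = _feature_cloud(rng, 2000, 100.0, 2.0)
        last = _feature_cloud(rng, 2000, 200.0, 2.0)
        clf = wetting.train_knn(first, last, k=10, seed=0)
        assert clf.validation_error == 0.0

    def test_k_larger_than_training_rejected(self, rng):
        first = _feature_cloud(rng, 5, 100.0, 2.0)
        last = _feature_cloud(rng, 5, 200.0, 2.0)
        with pytest.raises(ValidationError):
            wetting.train_knn(first, last, k=50, seed=0)

    def test_predictions_match_exhaustive_vote(self, rng):
        first = _feature_cloud(rng, 500, 100.0, 15.0)
        last = _feature_cloud(rng, 500, 130.0, 15.0)
        clf = wetting.train_knn(first, last, k=10, validation_fraction=0.0, seed=0)
        probes = _feature_cloud(rng, 100, 115.0, 20.0).matrix()
        got = clf.predict(probes)
        x = clf.standardize(probes)
        for i in range(len(x)):
            d = np.sqrt(((clf.train_features - x[i]) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[:10]
            votes = clf.train_labels[order].sum()
            expected = (
                votes * 2 > 10 if votes != 5 else clf.train_labels[order[0]]
            )
            assert got[i] == expected

    def test_documented_tie_break_uses_nearest_neighbour(self):
        # 5 dry / 5 wet neighbours at distinct distances; nearest is dry
        train = np.zeros((10, 5))
        train[:5, 3] = [0.5, 1.0, 1.0, 1.0, 1.0]  # dry at gray offsets
        train[5:, 3] = [0.9, 0.9, 0.9, 0.9, 0.9]  # wet slightly nearer than most dry
        clf = wetting.WettingClassifier(
            k=10,
            feature_mean=np.zeros(5),
            feature_sd=np.ones(5),
            train_features=train,
            train_labels=np.array([False] * 5 + [True] * 5),
            validation_error=0.0,
        )
        probe = np.zeros((1, 5))
        assert clf.predict(probe)[0] == False  # noqa: E712 - nearest is dry

    def test_validation_error_tracks_bayes_overlap(self, rng):
        # overlapping gray modes: the held-out error should approximate the
        # empirical misclassification rate of the ideal midpoint rule
        sd, sep = 12.0, 30.0
        first = _feature_cloud(rng, 20000, 100.0, sd)
        last = _feature_cloud(rng, 20000, 100.0 + sep, sd)
        clf = wetting.train_knn(first, last, k=10, seed=1)
        midpoint = 100.0 + sep / 2.0
        oracle_rate = 0.5 * (
            (first.gray >= midpoint).mean() + (last.gray < midpoint).mean()
        )
        assert clf.validation_error == pytest.approx(oracle_rate, abs=0.02)


class TestSeriesClassification:
    def test_training_scans_and_monotonicity(self, clean_series):
        series, truth = clean_series
        voi = truth.matrix_mask
        first = wetting.extract_features(series.volumes[0], voi)
        last = wetting.extract_features(series.volumes[-1], voi)
        clf = wetting.train_knn(first, last, k=10, seed=0)
        masks = wetting.classify_series(clf, series, voi)
        pen = wetting.penetration_profile(masks, voi, series.times_h)
        assert pen.wet_fraction[0] <= 0.02
        assert pen.wet_fraction[-1] >= 0.98
        assert np.all(np.diff(pen.wet_fraction) >= -0.01)
        for frac, true_frac in zip(pen.wet_fraction, truth.wet_fraction_per_time):
            assert frac == pytest.approx(true_frac, abs=0.02)

    def test_penetration_profile_trivia(self):
        shape = (3, 3, 3)
        voi = _full_mask(shape)
        empty = volio.BinaryMask(np.zeros(shape, bool))
        full = volio.BinaryMask(np.ones(shape, bool))
        pen = wetting.penetration_profile([empty, full], voi, [0.0, 1.0])
        assert pen.wet_fraction.tolist() == [0.0, 1.0]
        with pytest.raises(ValidationError):
            wetting.penetration_profile([], voi, [])

    def test_grid_mismatch_rejected(self, clean_series):
        series, truth = clean_series
        bad = volio.BinaryMask(np.ones((2, 2, 2), dtype=bool))
        first = wetting.extract_features(series.volumes[0], truth.matrix_mask)
        clf = wetting.train_knn(first, first, k=1, seed=0)
        with pytest.raises(ValidationError):
            wetting.classify_series(clf, series, bad)
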