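"""Regional segmentation, SDE features, Bhattacharyya, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofuse.phantom import make_cohort
from cardiofuse.regional import (LEVEL_SEGMENTS, SDE_FLOOR, area_feature,
                                 bhattacharyya, evaluate_loso, fit_classifier,
                                 partition_contour, radial_feature,
                                 shannon_differential_entropy)


def circle_contour(n=48, r=20.0, center=(0.0, 0.0)):
    a = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(a),
                            center[1] + r * np.sin(a)])


class TestPartition:
    def test_equal_angle_sectors_share_points_evenly(self):
        c = circle_contour(48)
        seg = partition_contour(c, landmark=c[0], level="mid")
        counts = np.bincount(seg.labels, minlength=6)
        assert np.all(np.abs(counts - 8) <= 1)

    def test_landmark_rotation_rotates_labels_cyclically(self):
        # landmarks off the sample grid so no point sits on a boundary
        c = circle_contour(48)
        lm0 = np.array([20 * np.cos(np.deg2rad(3.75)),
                        20 * np.sin(np.deg2rad(3.75))])
        lm1 = np.array([20 * np.cos(np.deg2rad(63.75)),
                        20 * np.sin(np.deg2rad(63.75))])
        seg0 = partition_contour(c, landmark=lm0, level="basal")
        seg1 = partition_contour(c, landmark=lm1, level="basal")
        assert np.array_equal(seg1.labels, (seg0.labels - 1) % 6)

    @pytest.mark.parametrize("level,n_expected",
                             [("apical", 4), ("mid", 6), ("basal", 6)])
    def test_segment_counts_per_level(self, level, n_expected):
        c = circle_contour(60)
        seg = partition_contour(c, landmark=c[5], level=level)
        assert seg.n_segments == n_expected
        assert len(np.unique(seg.labels)) == n_expected

    def test_landmark_off_plane_rejected(self):
        c3 = np.column_stack([circle_contour(24), np.zeros(24)])
        with pytest.raises(ValueError):
            partition_contour(c3, landmark=np.array([20.0, 0.0, 5.0]),
                              level="mid")


class TestSDE:
    def test_degenerate_distribution_reports_floor(self):
        assert shannon_differential_entropy(np.ones(50)) == SDE_FLOOR

    def test_gaussian_closed_form(self, rng):
        sigma = 0.3
        x = rng.normal(1.0, sigma, size=1000)
        expected = 0.5 * np.log(2 * np.pi * np.e * sigma ** 2)
        assert shannon_differential_entropy(x) == pytest.approx(expected,
                                                                abs=0.15)
        assert shannon_differential_entropy(x, method="kde") == pytest.approx(
            expected, abs=0.15)

    def test_matches_scipy_estimator_on_gaussian(self, rng):
        from scipy.stats import differential_entropy
        x = rng.normal(0.0, 2.0, size=2000)
        assert shannon_differential_entropy(x) == pytest.approx(
            float(differential_entropy(x)), abs=0.15)


class TestRadialFeature:
    def _traj(self, radii, n=24):
        a = 2 * np.pi * np.arange(n) / n
        unit = np.column_stack([np.cos(a), np.sin(a)])
        return np.array([r * unit for r in radii])

    def test_constant_radius_degenerate(self):
        traj = self._traj(np.ones(12))
        cen = np.zeros((12, 2))
        assert radial_feature(traj, cen) == SDE_FLOOR

    def test_scaling_invariance(self):
        rng = np.random.default_rng(1)
        radii = 1.0 + 0.2 * np.cos(2 * np.pi * np.arange(16) / 16)
        t1 = self._traj(radii)
        t5 = self._traj(5.0 * radii)
        cen = np.zeros((16, 2))
        assert radial_feature(t1, cen) == pytest.approx(
            radial_feature(t5, cen), abs=1e-12)

    def test_zero_radius_rejected(self):
        traj = np.zeros((10, 4, 2))
        with pytest.raises(ValueError):
            radial_feature(traj, np.zeros((10, 2)))


class TestAreaFeature:
    def test_rigid_translation_degenerate(self):
        poly = circle_contour(12, r=5.0)[:4]
        traj = np.array([poly + [k * 0.5, -k * 0.2] for k in range(10)])
        cen = traj.mean(axis=1)
        assert area_feature(traj, cen) == SDE_FLOOR

    def test_uniform_scaling_pushforward(self):
        s = 1.0 + 0.2 * np.cos(2 * np.pi * np.arange(16) / 16)
        poly = circle_contour(24, r=8.0)[:8]
        traj = np.array([f * poly for f in s])
        cen = np.zeros((16, 2))
        got = area_feature(traj, cen)
        expected = shannon_differential_entropy(s ** 2 / s[0] ** 2)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_shoelace_matches_shapely_on_quadrilateral(self):
        from shapely.geometry import Polygon
        from cardiofuse.regional import _shoelace
        quad = np.array([[0.0, 0.0], [4.0, 0.5], [5.0, 3.0], [0.5, 4.0]])
        assert _shoelace(quad) == pytest.approx(Polygon(quad).area, abs=1e-12)

    def test_wrap_around_segment_area_stable(self):
        # a segment whose points straddle the +-pi azimuth seam must still
        # produce a simple (non-self-intersecting) wedge polygon
        c = circle_contour(48, r=10.0)
        idx = np.r_[44:48, 0:4]
        s = 1.0 + 0.1 * np.cos(2 * np.pi * np.arange(16) / 16)
        traj = np.array([f * c[idx] for f in s])
        cen = np.zeros((16, 2))
        got = area_feature(traj, cen)
        expected = shannon_differential_entropy(s ** 2 / s[0] ** 2)
        assert got == pytest.approx(expected, abs=1e-9)


class TestBhattacharyya:
    def test_identical_distributions_zero(self):
        f = np.array([0.25, 0.5, 0.25])
        assert bhattacharyya(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        f = np.array([0.5, 0.5, 0.0, 0.0])
        g = np.array([0.0, 0.0, 0.3, 0.7])
        assert bhattacharyya(f, g) == pytest.approx(1.0)

    def test_binned_gaussians_match_quadrature_oracle(self):
        from scipy.stats import norm
        edges = np.linspace(-8, 10, 257)
        fN = np.diff(norm.cdf(edges, loc=0.0, scale=1.0))
        fA = np.diff(norm.cdf(edges, loc=2.0, scale=1.0))
        fN, fA = fN / fN.sum(), fA / fA.sum()
        got = bhattacharyya(fN, fA)
        # continuous coefficient for equal-variance Gaussians:
        # integral sqrt(fN fA) = exp(-delta^2 / 8)
        expected = np.sqrt(1.0 - np.exp(-(2.0 ** 2) / 8.0))
        assert got == pytest.approx(expected, abs=1e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random(16)
        g = rng.random(16)
        f, g = f / f.sum(), g / g.sum()
        b = bhattacharyya(f, g)
        assert 0.0 <= b <= 1.0
        assert b == pytest.approx(bhattacharyya(g, f), abs=1e-12)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya(np.array([1.1, -0.1]), np.array([0.5, 0.5]))


def _samples(X, y, subjects=None, level="mid"):
    df = pd.DataFrame({"sde_radial": X[:, 0], "sde_area": X[:, 1],
                       "label": y, "level": level})
    df["subject"] = subjects if subjects is not None else np.arange(len(y))
    return df


class TestClassifier:
    def test_separated_clusters_perfect_training_accuracy(self, rng):
        X0 = rng.normal([-3, -3], 0.3, size=(30, 2))
        X1 = rng.normal([3, 3], 0.3, size=(30, 2))
        df = _samples(np.vstack([X0, X1]), np.r_[np.zeros(30), np.ones(30)])
        clf = fit_classifier(df)
        pred = clf.predict(df[["sde_radial", "sde_area"]].to_numpy())
        assert np.mean(pred == df["label"]) == 1.0

    def test_symmetric_gaussians_boundary_at_midpoint(self, rng):
        n = 4000
        X0 = rng.normal([-1, 0], 1.0, size=(n, 2))
        X1 = rng.normal([1, 0], 1.0, size=(n, 2))
        df = _samples(np.vstack([X0, X1]), np.r_[np.zeros(n), np.ones(n)])
        clf = fit_classifier(df)
        assert clf.score([[0.0, 0.0]])[0] == pytest.approx(0.5, abs=0.05)
        assert clf.score([[-2.0, 0.0]])[0] < 0.2
        assert clf.score([[2.0, 0.0]])[0] > 0.8

    def test_sample_order_irrelevant(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        df = _samples(X, y)
        perm = rng.permutation(len(df))
        c1 = fit_classifier(df)
        c2 = fit_classifier(df.iloc[perm])
        grid = rng.normal(size=(20, 2))
        assert np.allclose(c1.score(grid), c2.score(grid), atol=1e-12)

    def test_single_class_rejected(self, rng):
        df = _samples(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            fit_classifier(df)


class TestLOSO:
    def test_perfect_scorer_full_marks(self, rng):
        n = 60
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([y * 10.0 - 5.0 + rng.normal(0, 0.1, n),
                             rng.normal(size=n)])
        df = _samples(X, y, subjects=np.arange(n) % 6)
        res = evaluate_loso(df)
        assert res["accuracy"] == 1.0
        assert res["auc"] == 1.0

    def test_label_independent_scores_give_chance_auc(self, rng):
        n = 2000
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 2))  # features carry no label information
        df = _samples(X, y, subjects=np.arange(n) % 10)
        res = evaluate_loso(df)
        assert res["auc"] == pytest.approx(0.5, abs=0.03)

    def test_roc_monotone(self, rng):
        df = make_cohort(n_subjects=8, n_abnormal=3, seed=2, K=12)
        res = evaluate_loso(df)
        assert np.all(np.diff(res["roc"]["fpr"]) >= 0)
        assert np.all(np.diff(res["roc"]["tpr"]) >= 0)

    def test_phantom_cohort_separates_hypokinesia(self):
        df = make_cohort(n_subjects=20, n_abnormal=7, seed=0)
        res = evaluate_loso(df)
        assert res["accuracy"] > 0.85
        assert res["auc"] > 0.9
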