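import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from owaci.errors import (
    DegenerateSeriesError,
    SingularCovarianceError,
    ValidationError,
)
from owaci.quality import (
    discriminant_power_eq4,
    discriminant_power_reported,
    explanatory_power,
    mahalanobis_distances,
    outlier_proportion,
    quality_report,
)


def rank_then_pearson(a, b):
    """Independent oracle: midranks by hand, then the plain Pearson formula."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


class TestExplanatoryPower:
    def test_identical_ranking_is_one(self):
        scores = [0.1, 0.4, 0.5, 0.9]
        assert explanatory_power(scores, np.exp(scores)) == pytest.approx(1.0)

    def test_reversed_ranking_is_minus_one(self):
        assert explanatory_power([1, 2, 3, 4], [9, 7, 5, 2]) == pytest.approx(-1.0)

    def test_midranks_match_rank_then_pearson_oracle(self):
        scores = [1, 2, 3, 4]
        external = [10, 10, 30, 40]   # tie -> midranks (1.5, 1.5, 3, 4)
        assert explanatory_power(scores, external) == pytest.approx(
            rank_then_pearson(scores, external), abs=1e-12)

    def test_all_tied_scores_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            explanatory_power([0.5, 0.5, 0.5], [1, 2, 3])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=40,
                    unique=True))
    @settings(max_examples=150, deadline=None)
    def test_invariant_under_monotone_transforms(self, scores):
        """Rank correlation ignores any strictly increasing relabeling."""
        rng = np.random.default_rng(7)
        external = rng.uniform(0, 100, len(scores))
        if np.unique(external).size == 1:
            return
        base = explanatory_power(scores, external)
        # strictly increasing maps that are exact in binary floating point
        warped = explanatory_power(8.0 * np.asarray(scores),
                                   0.25 * external)
        assert warped == pytest.approx(base, abs=1e-12)


class TestDiscriminantPower:
    def test_eq4_all_ones_is_zero(self):
        assert discriminant_power_eq4([1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_eq4_uniform_quarter_is_one(self):
        assert discriminant_power_eq4([0.25] * 4) == pytest.approx(1.0)

    def test_eq4_two_scores_closed_form(self):
        expected = -(0.2 * np.log(0.2) + 0.8 * np.log(0.8)) / np.log(2)
        assert discriminant_power_eq4([0.2, 0.8]) == pytest.approx(expected)

    def test_eq4_zero_scores_contribute_nothing(self):
        assert np.isfinite(discriminant_power_eq4([0.0, 0.5, 1.0]))

    def test_reported_distinct_scores_is_log2_n(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 54)
        assert discriminant_power_reported(scores) == pytest.approx(
            np.log2(54), abs=1e-12)

    def test_reported_identical_scores_is_zero(self):
        assert discriminant_power_reported([0.3] * 10) == pytest.approx(0.0)

    def test_reported_two_equiprobable_classes_is_one_bit(self):
        assert discriminant_power_reported([0.2, 0.2, 0.7, 0.7]) == \
            pytest.approx(1.0)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_reported_bounded_by_log2_n(self, scores):
        h = discriminant_power_reported(scores)
        assert -1e-12 <= h <= np.log2(len(scores)) + 1e-12
        distinct = np.unique(scores).size == len(scores)
        if distinct:
            assert h == pytest.approx(np.log2(len(scores)), abs=1e-9)


class TestMahalanobis:
    def test_unit_at_mean_has_zero_distance(self):
        scores = np.array([0.2, 0.4, 0.3, 0.6, 0.5])
        ext = np.array([10.0, 31, 20, 50, 44])
        # unit 1 sits exactly at the bivariate mean (0.4, 31)
        d = mahalanobis_distances(scores, ext)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_toy(self):
        """Orthogonal unit-variance axes: one-sigma offset gives distance 1."""
        s = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        s = s / s.std(ddof=1)
        e = e / e.std(ddof=1)
        d = mahalanobis_distances(s, e, rescale=False)
        assert d[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_2x2_inversion(self):
        """Five-point set against a by-hand 2x2 inverse."""
        scores = np.array([0.12, 0.47, 0.33, 0.81, 0.62])
        ext = np.array([5.0, 42.0, 18.0, 90.0, 33.0])
        e01 = (ext - ext.min()) / (ext.max() - ext.min())
        X = np.column_stack([scores, e01])
        dvec = X - X.mean(axis=0)
        a = np.sum(dvec[:, 0] ** 2) / 4
        b = np.sum(dvec[:, 0] * dvec[:, 1]) / 4
        c = np.sum(dvec[:, 1] ** 2) / 4
        det = a * c - b * b
        inv = np.array([[c, -b], [-b, a]]) / det
        expected = np.array([row @ inv @ row for row in dvec])
        np.testing.assert_allclose(mahalanobis_distances(scores, ext),
                                   expected, atol=1e-10)

    def test_mean_distance_identity(self):
        """mean(eta^2) = 2 (delta-1)/delta for the classical estimator."""
        rng = np.random.default_rng(11)
        for n in (10, 54, 200):
            s = rng.uniform(0, 1, n)
            e = 0.5 * s + rng.normal(0, 0.2, n)
            e = 100 * (e - e.min()) / (e.max() - e.min())
            d = mahalanobis_distances(s, e)
            assert d.mean() == pytest.approx(2 * (n - 1) / n, abs=1e-9)

    def test_collinear_series_rejected(self):
        s = np.array([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(SingularCovarianceError):
            mahalanobis_distances(s, 100 * s)


class TestOutlierProportion:
    def test_all_zero_distances_flag_nothing(self):
        B, flags = outlier_proportion(np.zeros(10))
        assert B == 0.0 and not flags.any()

    def test_two_of_54_gives_paper_ratio(self):
        d = np.zeros(54)
        d[[3, 17]] = 50.0
        B, flags = outlier_proportion(d)
        assert flags.sum() == 2
        assert B == pytest.approx(2 / 54)

    def test_monotone_non_increasing_in_quantile(self):
        rng = np.random.default_rng(3)
        d = rng.chisquare(2, 500)
        props = [outlier_proportion(d, q)[0] for q in (0.8, 0.9, 0.95, 0.99)]
        assert all(a >= b for a, b in zip(props, props[1:]))

    def test_invalid_quantile(self):
        with pytest.raises(ValidationError):
            outlier_proportion([1.0], quantile=1.5)


def test_quality_report_is_internally_consistent():
    rng = np.random.default_rng(5)
    scores = rng.uniform(0, 1, 54)
    ext = 100 * np.clip(scores + rng.normal(0, 0.3, 54), 0, 1)
    rep = quality_report(scores, ext)
    assert rep.outlier_proportion == pytest.approx(rep.flags.mean())
    np.testing.assert_array_equal(rep.flags, rep.distances > rep.threshold)
    assert -1 <= rep.explanatory_power <= 1
    assert rep.discriminant_power_eq4 >= 0
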