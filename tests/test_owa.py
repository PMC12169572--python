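import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from owaci.errors import (
    DegenerateColumnError,
    InfeasibleEmphasisError,
    ValidationError,
)
from owaci.owa import (
    EmphasisSpec,
    build_owa_weights,
    minmax_normalize,
    orient,
    owa_aggregate,
    owa_aggregate_matrix,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)
unit_floats = st.floats(0.0, 1.0, allow_nan=False)


def brute_owa(values, weights):
    """Independent oracle: explicit descending sort and position-wise sum."""
    ordered = sorted(values, reverse=True)
    return sum(b * a for b, a in zip(weights, ordered))


class TestNormalize:
    def test_linear_map_endpoints(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_two_point_case(self):
        np.testing.assert_allclose(minmax_normalize([0.22, 0.87]), [0, 1])

    def test_constant_column_raises(self):
        with pytest.raises(DegenerateColumnError, match="constant"):
            minmax_normalize([5, 5, 5])

    def test_missing_values_stay_missing(self):
        out = minmax_normalize([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0, 1])

    @given(st.lists(finite_floats, min_size=2, max_size=30),
           st.floats(0.1, 100), st.floats(-1e3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_affine_invariance(self, vals, scale, shift):
        """Positive scaling plus shift leaves the normalized column unchanged."""
        arr = np.asarray(vals)
        if np.ptp(arr) < 1e-6 * max(1.0, np.abs(arr).max()):
            return  # effectively constant, covered by the degenerate case
        base = minmax_normalize(arr)
        moved = minmax_normalize(arr * scale + shift)
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestOrient:
    def test_protective_reflects(self):
        np.testing.assert_allclose(
            orient([0, 0.5, 1], "protective"), [1, 0.5, 0])

    def test_adversity_increasing_identity(self):
        np.testing.assert_allclose(
            orient([0, 0.5, 1], "adversity_increasing"), [0, 0.5, 1])

    def test_double_reflection_is_identity(self):
        col = np.array([0.1, 0.4, 0.9])
        np.testing.assert_allclose(
            orient(orient(col, "protective"), "protective"), col)

    def test_out_of_range_rejected(self):
        with pytest.raises(Exception, match=r"\[0, 1\]"):
            orient([0.5, 1.5], "protective")


class TestWeights:
    def test_uniform(self):
        np.testing.assert_allclose(build_owa_weights(4), [0.25] * 4)

    def test_negative_quarter_drops_top(self):
        beta = build_owa_weights(4, EmphasisSpec("negative", 0.25))
        np.testing.assert_allclose(beta, [0, 1 / 3, 1 / 3, 1 / 3])

    def test_positive_quarter_drops_bottom(self):
        beta = build_owa_weights(4, EmphasisSpec("positive", 0.25))
        np.testing.assert_allclose(beta, [1 / 3, 1 / 3, 1 / 3, 0])

    def test_small_intensity_still_zeroes_one(self):
        beta = build_owa_weights(10, EmphasisSpec("negative", 0.05))
        assert beta[0] == 0 and np.count_nonzero(beta == 0) == 1

    def test_infeasible_emphasis(self):
        with pytest.raises(InfeasibleEmphasisError):
            build_owa_weights(1, EmphasisSpec("negative", 0.9))

    @given(st.integers(2, 40), st.sampled_from(["none", "negative", "positive"]),
           st.floats(0, 0.99))
    @settings(max_examples=300, deadline=None)
    def test_weights_always_sum_to_one(self, rho, direction, intensity):
        if direction == "none":
            intensity = 0.0
        emph = EmphasisSpec(direction, intensity)
        if emph.n_zeroed(rho) >= rho:
            return
        beta = build_owa_weights(rho, emph)
        assert abs(beta.sum() - 1.0) < 1e-12
        assert (beta >= 0).all() and (beta <= 1).all()

    def test_direction_none_forbids_intensity(self):
        with pytest.raises(ValidationError):
            EmphasisSpec("none", 0.2)


class TestAggregate:
    def test_uniform_is_mean(self):
        assert owa_aggregate([0.2, 0.4, 0.6], [1 / 3] * 3) == pytest.approx(0.4)

    def test_drop_top_example(self):
        """Ordered (0.9, 0.5, 0.3, 0.1); mean of the bottom three is 0.3."""
        score = owa_aggregate([0.9, 0.1, 0.5, 0.3], [0, 1 / 3, 1 / 3, 1 / 3])
        assert score == pytest.approx(0.3)

    def test_idempotence_on_constant(self):
        beta = build_owa_weights(5, EmphasisSpec("negative", 0.3))
        assert owa_aggregate([0.7] * 5, beta) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            owa_aggregate([], [])

    def test_tie_at_weight_boundary_is_invariant(self):
        """Equal values straddling the zero/nonzero boundary give one score."""
        beta = [0, 0.5, 0.5]
        for perm in ([0.8, 0.8, 0.2], [0.2, 0.8, 0.8], [0.8, 0.2, 0.8]):
            assert owa_aggregate(perm, beta) == pytest.approx(
                owa_aggregate([0.8, 0.8, 0.2], beta))

    @given(st.lists(unit_floats, min_size=2, max_size=8), st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_and_bounds(self, vals, data):
        rho = len(vals)
        emph = data.draw(st.sampled_from(
            [EmphasisSpec(), EmphasisSpec("negative", 0.25),
             EmphasisSpec("positive", 0.4)]))
        if emph.n_zeroed(rho) >= rho:
            return
        beta = build_owa_weights(rho, emph)
        score = owa_aggregate(vals, beta)
        assert score == pytest.approx(brute_owa(vals, beta), abs=1e-12)
        assert min(vals) - 1e-12 <= score <= max(vals) + 1e-12

    @given(st.lists(unit_floats, min_size=2, max_size=8), st.randoms())
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, vals, rnd):
        beta = build_owa_weights(len(vals))
        shuffled = list(vals)
        rnd.shuffle(shuffled)
        assert owa_aggregate(shuffled, beta) == pytest.approx(
            owa_aggregate(vals, beta), abs=1e-12)

    def test_monotone_in_every_input(self):
        """Raising any single input never lowers the score (vs brute oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            rho = int(rng.integers(2, 8))
            vals = rng.uniform(0, 1, rho)
            emph = [EmphasisSpec(), EmphasisSpec("negative", 0.3),
                    EmphasisSpec("positive", 0.3)][int(rng.integers(3))]
            beta = build_owa_weights(rho, emph)
            base = owa_aggregate(vals, beta)
            i = int(rng.integers(rho))
            bumped = vals.copy()
            bumped[i] = min(1.0, bumped[i] + rng.uniform(0, 0.5))
            assert brute_owa(bumped, beta) >= base - 1e-12
            assert owa_aggregate(bumped, beta) >= base - 1e-12


def test_matrix_aggregation_reweights_missing_cells():
    """A NaN cell drops out and the weights are rebuilt over the rest."""
    mat = np.array([[0.2, 0.4, 0.6],
                    [0.2, np.nan, 0.6]])
    scores = owa_aggregate_matrix(mat, EmphasisSpec())
    np.testing.assert_allclose(scores, [0.4, 0.4])
    neg = owa_aggregate_matrix(mat, EmphasisSpec("negative", 0.34))
    # row 0: drop 0.6, mean(0.2, 0.4); row 1: drop 0.6, mean(0.2)
    np.testing.assert_allclose(neg, [0.3, 0.2])
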