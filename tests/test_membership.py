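"""Trapezoidal grade partitions: split points, membership vectors, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deserisk import (
    GradeBoundaries,
    canonical_config,
    derive_split_points,
    grade_layers,
    membership_vector,
)
from deserisk.errors import ValidationError
from deserisk.membership import partition_for

from conftest import make_layer


class TestDeriveSplitPoints:
    def test_increasing_hand_case(self):
        p = derive_split_points(GradeBoundaries((1, 2, 3, 4), "increasing"))
        assert p.splits == pytest.approx(
            (0.75, 1.25, 1.75, 2.25, 2.75, 3.25, 3.75, 5.0)
        )

    def test_decreasing_mirrors_increasing(self):
        p = derive_split_points(GradeBoundaries((4, 3, 2, 1), "decreasing"))
        assert p.splits == pytest.approx(
            (5.0, 3.75, 3.25, 2.75, 2.25, 1.75, 1.25, 0.75)
        )

    def test_zero_first_boundary_collapses_outer_point(self):
        p = derive_split_points(GradeBoundaries((0, 2, 3, 4), "increasing"))
        assert p.splits[0] == 0.0  # a1- = b1 when |b1| = 0

    def test_literal_outer_variant(self):
        p = derive_split_points(GradeBoundaries((1, 2, 3, 4), "increasing"),
                                literal_outer=True)
        assert p.splits[-1] == pytest.approx(4.25)  # b4 + b1/4 as tabulated

    def test_wrong_ordering_rejected(self):
        with pytest.raises(ValidationError):
            GradeBoundaries((1, 2, 3, 4), "decreasing")


class TestMembershipVector:
    @pytest.fixture
    def inc(self):
        return derive_split_points(GradeBoundaries((1, 2, 3, 4), "increasing"))

    @pytest.fixture
    def dec(self):
        return derive_split_points(GradeBoundaries((4, 3, 2, 1), "decreasing"))

    @pytest.mark.parametrize(
        "x, expected",
        [
            (1.5, [0, 1, 0, 0, 0]),        # grade-2 plateau
            (1.0, [0.5, 0.5, 0, 0, 0]),    # midpoint of the first ramp
            (6.0, [0, 0, 0, 0, 1]),        # beyond the outer split
            (0.0, [1, 0, 0, 0, 0]),        # below the first split
            (1.25, [0, 1, 0, 0, 0]),       # closed plateau edge
        ],
    )
    def test_increasing_hand_cases(self, inc, x, expected):
        np.testing.assert_allclose(membership_vector(x, inc), expected, atol=1e-12)

    def test_decreasing_high_value_is_grade_one(self, dec):
        np.testing.assert_allclose(
            membership_vector(6.0, dec), [1, 0, 0, 0, 0], atol=1e-12
        )
        np.testing.assert_allclose(
            membership_vector(0.0, dec), [0, 0, 0, 0, 1], atol=1e-12
        )

    def test_non_finite_propagates_as_nan(self, inc):
        out = membership_vector([np.nan, 2.5], inc)
        assert np.isnan(out[0]).all()
        assert np.isfinite(out[1]).all()

    def test_mirror_duality(self):
        """Decreasing membership at x equals increasing membership at -x
        with negated boundaries and reversed grades."""
        b = (7.0, 5.0, 2.0, 1.0)
        dec = derive_split_points(GradeBoundaries(b, "decreasing"))
        inc = derive_split_points(
            GradeBoundaries(tuple(-v for v in b), "increasing")
        )
        xs = np.linspace(-2, 10, 301)
        np.testing.assert_allclose(
            membership_vector(xs, dec), membership_vector(-xs, inc), atol=1e-12
        )

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(-50, 50))
    def test_partition_of_unity(self, x):
        inc = derive_split_points(GradeBoundaries((1, 2, 3, 4), "increasing"))
        v = membership_vector(x, inc)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert (v >= 0).all() and (v <= 1).all()

    def test_partition_of_unity_all_canonical_indicators(self):
        rng = np.random.default_rng(12)
        for spec in canonical_config():
            p = partition_for(spec)
            lo, hi = spec.envelope
            width = hi - lo
            xs = rng.uniform(lo - width, hi + width, 10_000)
            v = membership_vector(xs, p)
            np.testing.assert_allclose(v.sum(axis=-1), 1.0, atol=1e-12)

    def test_monotone_expected_grade(self):
        rng = np.random.default_rng(13)
        g = np.arange(1, 6)
        for spec in canonical_config():
            p = partition_for(spec)
            lo, hi = spec.envelope
            xs = np.sort(rng.uniform(lo - 1, hi + 1, 500))
            expected = membership_vector(xs, p) @ g
            diffs = np.diff(expected)
            if p.direction == "increasing":
                assert (diffs >= -1e-12).all(), spec.name
            else:
                assert (diffs <= 1e-12).all(), spec.name


class TestGradeLayers:
    def test_constant_plateau_layer_gives_basis_vectors(self, config):
        spec = config["cultivation_rate"]  # boundaries 11, 33, 56, 80
        layer = make_layer(np.full((4, 4), 45.0), spec.name)  # grade-3 plateau
        result = grade_layers(layer, spec)
        np.testing.assert_allclose(
            result.memberships, np.tile([0, 0, 1, 0, 0], (4, 4, 1)), atol=1e-12
        )

    def test_masked_cells_stay_masked(self, config):
        spec = config["cultivation_rate"]
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        layer = make_layer(np.full((2, 2), 45.0), spec.name, mask=mask)
        result = grade_layers(layer, spec)
        assert result.nodata_mask[0, 0]
        assert np.isnan(result.memberships[0, 0]).all()

    def test_name_mismatch_rejected(self, config):
        layer = make_layer([[1.0]], "not_an_indicator")
        with pytest.raises(ValidationError):
            grade_layers(layer, config["precipitation"])

    def test_random_layer_sums_to_one(self, config):
        spec = config["precipitation"]
        rng = np.random.default_rng(21)
        layer = make_layer(rng.uniform(300, 460, (100, 100)), spec.name)
        result = grade_layers(layer, spec)
        np.testing.assert_allclose(
            result.memberships.sum(axis=-1), 1.0, atol=1e-12
        )
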