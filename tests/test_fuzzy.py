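"""Factor evaluation, defuzzification, DDRI aggregation, grading and zoning."""

import numpy as np
import pytest

from deserisk import (
    FuzzyResult,
    RiskModel,
    WeightVector,
    area_ratio,
    ddri,
    defuzzify,
    factor_evaluate,
    grade_risk,
    zonal_stats,
)
from deserisk.errors import ValidationError

from conftest import make_layer


def fuzzy_from_vectors(vectors, name="f"):
    """FuzzyResult from an (rows, cols, 5) array of membership vectors."""
    arr = np.asarray(vectors, dtype=float)
    return FuzzyResult(
        name=name, memberships=arr, nodata_mask=np.zeros(arr.shape[:2], dtype=bool)
    )


class TestFactorEvaluate:
    def test_single_indicator_is_identity(self):
        b = fuzzy_from_vectors([[[0.2, 0.3, 0.5, 0, 0]]], "a")
        out = factor_evaluate([b], WeightVector(["a"], [1.0]))
        np.testing.assert_allclose(out.memberships, b.memberships, atol=1e-12)

    def test_convex_mixture_of_basis_rows(self):
        r1 = fuzzy_from_vectors([[[1, 0, 0, 0, 0]]], "a")
        r2 = fuzzy_from_vectors([[[0, 1, 0, 0, 0]]], "b")
        out = factor_evaluate([r1, r2], WeightVector(["a", "b"], [0.5, 0.5]))
        np.testing.assert_allclose(out.memberships[0, 0], [0.5, 0.5, 0, 0, 0])

    def test_hand_matrix_product(self):
        r1 = fuzzy_from_vectors([[[0.4, 0.6, 0, 0, 0]]], "a")
        r2 = fuzzy_from_vectors([[[0, 0.2, 0.8, 0, 0]]], "b")
        out = factor_evaluate([r1, r2], WeightVector(["a", "b"], [0.25, 0.75]))
        np.testing.assert_allclose(out.memberships[0, 0], [0.1, 0.3, 0.6, 0, 0],
                                   atol=1e-12)

    def test_weights_renormalized_within_factor(self):
        r1 = fuzzy_from_vectors([[[1, 0, 0, 0, 0]]], "a")
        r2 = fuzzy_from_vectors([[[0, 0, 1, 0, 0]]], "b")
        # weights sum to 0.5: must act like (0.6, 0.4)
        out = factor_evaluate([r1, r2], WeightVector.from_raw(["a", "b"], [0.3, 0.2]))
        np.testing.assert_allclose(out.memberships[0, 0], [0.6, 0, 0.4, 0, 0])

    def test_output_normalized(self):
        rng = np.random.default_rng(8)
        results, names = [], []
        for j in range(3):
            raw = rng.dirichlet(np.ones(5), size=(4, 4))
            results.append(fuzzy_from_vectors(raw, f"i{j}"))
            names.append(f"i{j}")
        out = factor_evaluate(results, WeightVector.from_raw(names, rng.uniform(0.1, 1, 3)))
        np.testing.assert_allclose(out.memberships.sum(axis=-1), 1.0, atol=1e-12)

    def test_name_mismatch_rejected(self):
        b = fuzzy_from_vectors([[[1, 0, 0, 0, 0]]], "a")
        with pytest.raises(ValidationError):
            factor_evaluate([b], WeightVector(["z"], [1.0]))


class TestDefuzzify:
    scores = (0.1, 0.3, 0.5, 0.7, 0.9)

    @pytest.mark.parametrize(
        "vector, expected",
        [
            ([0, 0, 1, 0, 0], 0.5),
            ([0.5, 0.5, 0, 0, 0], 0.2),
            ([0, 0, 0, 0, 1], 0.9),
        ],
    )
    def test_hand_cases(self, vector, expected):
        b = fuzzy_from_vectors([[vector]])
        layer = defuzzify(b, self.scores)
        assert layer.values[0, 0] == pytest.approx(expected)

    def test_output_within_score_range(self):
        rng = np.random.default_rng(15)
        b = fuzzy_from_vectors(rng.dirichlet(np.ones(5), size=(6, 6)))
        vals = defuzzify(b, self.scores).unmasked()
        assert vals.min() >= 0.1 - 1e-12 and vals.max() <= 0.9 + 1e-12


class TestDdri:
    table_model = RiskModel()  # factor weights 0.4088/0.2055/0.1992/0.1865

    def make_factors(self, h, e, v, r):
        return (make_layer([[h]]), make_layer([[e]]), make_layer([[v]]),
                make_layer([[r]]))

    def test_maximal_risk(self):
        out = ddri(*self.make_factors(1, 1, 1, 0), self.table_model)
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_exponents_sum_to_one_identity(self):
        out = ddri(*self.make_factors(0.5, 0.5, 0.5, 0.5), self.table_model)
        assert out.values[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_geometric_annihilation(self):
        assert ddri(*self.make_factors(0, 0.5, 0.5, 0.5)).values[0, 0] == 0.0
        assert ddri(*self.make_factors(0.5, 0.5, 0.5, 1.0)).values[0, 0] == 0.0

    def test_uniform_factor_identity(self):
        for c in (0.2, 0.5, 0.8):
            out = ddri(*self.make_factors(c, c, c, 1 - c), self.table_model)
            assert out.values[0, 0] == pytest.approx(c, abs=1e-12)

    def test_monotone_in_each_factor(self):
        rng = np.random.default_rng(17)
        base = rng.uniform(0.05, 0.95, size=(10_000, 4))
        bumped = np.minimum(base + 0.03, 1.0)
        shape = (100, 100)

        def index(h, e, v, r):
            return ddri(
                make_layer(h.reshape(shape)), make_layer(e.reshape(shape)),
                make_layer(v.reshape(shape)), make_layer(r.reshape(shape)),
                self.table_model,
            ).values.ravel()

        ref = index(*base.T)
        for col in range(3):  # hazard, exposure, vulnerability: non-decreasing
            cols = base.copy()
            cols[:, col] = bumped[:, col]
            assert (index(*cols.T) >= ref - 1e-12).all()
        cols = base.copy()
        cols[:, 3] = bumped[:, 3]  # restorability: non-increasing
        assert (index(*cols.T) <= ref + 1e-12).all()

    def test_out_of_range_factor_named(self):
        with pytest.raises(ValidationError, match="hazard"):
            ddri(*self.make_factors(1.5, 0.5, 0.5, 0.5))

    def test_product_aggregation_flag(self):
        out = ddri(*self.make_factors(0.5, 0.5, 0.5, 0.5), self.table_model,
                   aggregation="product")
        w = self.table_model.factor_weights
        expected = (0.5 ** 4) * w["hazard"] * w["exposure"] * w["vulnerability"] * w["restorability"]
        assert out.values[0, 0] == pytest.approx(expected)


class TestGradeRisk:
    @pytest.mark.parametrize(
        "value, grade",
        [(0.29, 1), (0.30, 2), (0.47, 2), (0.50, 3), (0.63, 3), (0.78, 4),
         (0.80, 5), (1.0, 5), (0.01, 1)],
    )
    def test_half_open_interval_lookup(self, value, grade):
        out = grade_risk(make_layer([[value]]))
        assert out.values[0, 0] == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            grade_risk(make_layer([[1.2]]))
        with pytest.raises(ValidationError):
            grade_risk(make_layer([[0.0]]))


class TestZonalStats:
    def test_single_region_uniform_grade(self):
        grades = make_layer(np.full((3, 3), 3.0))
        risk = make_layer(np.full((3, 3), 0.5))
        regions = make_layer(np.ones((3, 3)))
        table = zonal_stats(grades, risk, regions)
        row = table.loc[1]
        assert row["ratio_middle"] == 1.0
        assert row["mean_ddri"] == pytest.approx(0.5)

    def test_global_ratios_weight_regions_by_cells(self):
        grades = make_layer(np.array([[1.0, 1.0], [5.0, 5.0]]))
        risk = make_layer(np.array([[0.1, 0.1], [0.9, 0.9]]))
        regions = make_layer(np.array([[1.0, 1.0], [2.0, 2.0]]))
        table = zonal_stats(grades, risk, regions)
        assert table.loc["global", "ratio_very_low"] == pytest.approx(0.5)
        assert table.loc["global", "ratio_very_high"] == pytest.approx(0.5)

    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(19)
        grade_vals = rng.integers(1, 6, size=(10, 10)).astype(float)
        grades = make_layer(grade_vals)
        risk = make_layer(rng.uniform(0.01, 1.0, (10, 10)))
        regions = make_layer(np.ones((10, 10)))
        table = zonal_stats(grades, risk, regions)
        for g, label in enumerate(
            ["very_low", "low", "middle", "high", "very_high"], start=1
        ):
            assert table.loc[1, f"ratio_{label}"] == pytest.approx(
                (grade_vals == g).mean()
            )

    def test_ratios_sum_to_one_per_region(self):
        rng = np.random.default_rng(20)
        grades = make_layer(rng.integers(1, 6, size=(8, 8)).astype(float))
        risk = make_layer(rng.uniform(0.01, 1.0, (8, 8)))
        regions = make_layer(rng.integers(1, 4, size=(8, 8)).astype(float))
        table = zonal_stats(grades, risk, regions)
        ratio_cols = [c for c in table.columns if c.startswith("ratio_")]
        np.testing.assert_allclose(table[ratio_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_unlabeled_cells_warn_and_excluded(self):
        grades = make_layer(np.full((2, 2), 2.0))
        risk = make_layer(np.full((2, 2), 0.4))
        region_mask = np.zeros((2, 2), dtype=bool)
        region_mask[0, 0] = True
        regions = make_layer(np.ones((2, 2)), mask=region_mask)
        with pytest.warns(UserWarning, match="no region label"):
            table = zonal_stats(grades, risk, regions)
        assert table.loc[1, "cell_count"] == 3


class TestAreaRatio:
    def test_worked_land_use_shares(self):
        assert area_ratio(2424.87, 8120) == pytest.approx(29.9)
        assert area_ratio(801.97, 8120) == pytest.approx(9.9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            area_ratio(1.0, 0.0)
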