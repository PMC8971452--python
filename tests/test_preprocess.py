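import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plscova.datatypes import MedicationRecord, VisitRecord
from plscova.preprocess import (
    add_drug_dummies,
    adjust_covariates,
    boxcox_zscore,
    compute_alr,
    compute_ledd,
    filter_nonvariable,
    fit_slopes,
    group_updrs_subscores,
    load_subscore_map,
    rank_transform,
    zscore,
)

rng = np.random.default_rng(42)


def _visit(subject, t, fill=1.0, state="ON", overrides=None):
    mapping = load_subscore_map()
    items = {i: fill for group in mapping.values() for i in group}
    if overrides:
        items.update(overrides)
    return VisitRecord(subject, t, items, state)


class TestAdjustCovariates:
    def test_orthogonal_covariate_leaves_column_unchanged(self):
        n = 64
        cov = pd.DataFrame({"c": np.tile([-1.0, 1.0], n // 2)})
        y = pd.DataFrame({"y": np.repeat([-1.0, 1.0], n // 2)})  # orthogonal to cov
        adjusted = adjust_covariates(y, cov, method="ols")
        np.testing.assert_allclose(adjusted["y"], y["y"], atol=1e-10)

    def test_exact_linear_dependence_leaves_intercept(self):
        cov = pd.DataFrame({"c": rng.normal(size=50)})
        y = pd.DataFrame({"y": 3.0 + 2.0 * cov["c"]})
        adjusted = adjust_covariates(y, cov, method="huber")
        np.testing.assert_allclose(adjusted["y"], 3.0, atol=1e-6)

    def test_huber_matches_ols_without_outliers(self):
        """With all residuals inside the Huber threshold (no outliers),
        the M-estimate coincides with the OLS closed form."""
        n = 40
        c = np.repeat([-1.0, 1.0], n // 2)
        e = np.tile([0.2, -0.2], n // 2)  # orthogonal to the design, no tail
        cov = pd.DataFrame({"c": c})
        y = pd.DataFrame({"y": 1.0 + 0.5 * c + e})
        h = adjust_covariates(y, cov, method="huber")
        o = adjust_covariates(y, cov, method="ols")
        np.testing.assert_allclose(h["y"], o["y"], atol=1e-6)
        np.testing.assert_allclose(o["y"], 1.0 + e, atol=1e-10)  # intercept + residuals

    def test_ols_residuals_orthogonal_to_covariates(self):
        cov = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = pd.DataFrame({"y": rng.normal(size=100)})
        adjusted = adjust_covariates(y, cov, method="ols")
        resid = adjusted["y"] - adjusted["y"].mean()
        for c in cov.columns:
            assert abs(np.corrcoef(resid, cov[c])[0, 1]) < 1e-10

    def test_collinear_covariates_reported(self):
        cov = pd.DataFrame({"a": rng.normal(size=30)})
        cov["b"] = 2 * cov["a"]
        y = pd.DataFrame({"y": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear"):
            adjust_covariates(y, cov)


class TestBoxCoxZscore:
    def test_normal_column_gets_lambda_near_one(self):
        x = pd.DataFrame({"x": rng.normal(5, 1, size=2000)})
        adj = boxcox_zscore(x)
        assert abs(adj.lambdas["x"] - 1.0) < 0.25
        # output is the input re-standardised, up to the mild transform
        assert np.corrcoef(adj.values["x"], x["x"])[0, 1] > 0.999

    def test_fixed_lambda_zero_is_log(self):
        x = pd.DataFrame({"x": [1.0, np.e, np.e ** 2]})
        adj = boxcox_zscore(x, lmbda=0.0)
        expected = zscore(pd.DataFrame({"x": [0.0, 1.0, 2.0]}))
        np.testing.assert_allclose(adj.values["x"], expected["x"], atol=1e-12)

    def test_output_standardised_and_shift_recorded(self):
        x = pd.DataFrame({"x": rng.exponential(2.0, size=300) - 1.0})
        adj = boxcox_zscore(x)
        assert abs(adj.values["x"].mean()) < 1e-8
        assert abs(adj.values["x"].std(ddof=1) - 1) < 1e-8
        assert adj.shifts["x"] == pytest.approx(1.0 - x["x"].min())

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox_zscore(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestRankTransform:
    @pytest.mark.parametrize(
        "data, expected",
        [([3.2, 1.1, 5.0], [2, 1, 3]), ([1, 1, 2], [1.5, 1.5, 3])],
    )
    def test_examples(self, data, expected):
        out = rank_transform(pd.DataFrame({"x": data}))
        np.testing.assert_array_equal(out["x"], expected)

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_monotone_invariance(self, data):
        df = pd.DataFrame({"x": np.array(data) / 20.0})
        np.testing.assert_array_equal(
            rank_transform(df)["x"], rank_transform(np.exp(df / 25.0))["x"])


class TestFitSlopes:
    def test_exact_line(self):
        visits = [_visit("S1", t, fill=0.0, overrides=None) for t in (0.0, 1.0, 2.0)]
        # totals 10, 12, 14 via the speech item plus spread over items
        for v, total in zip(visits, (10, 12, 14)):
            per_item = total / 33.0
            v.items = {k: per_item for k in v.items}
        slopes = fit_slopes(visits)
        assert slopes.values.loc["S1", "total"] == pytest.approx(2.0)

    def test_two_visit_subject_excluded(self):
        visits = [_visit("A", t) for t in (0, 1, 2)] + [_visit("B", t) for t in (0, 1)]
        slopes = fit_slopes(visits)
        assert list(slopes.values.index) == ["A"]

    def test_all_excluded_raises(self):
        visits = [_visit("B", t) for t in (0, 1)]
        with pytest.raises(ValueError, match="inclusion"):
            fit_slopes(visits)

    def test_off_state_visits_not_counted(self):
        visits = [_visit("A", t) for t in (0, 1, 2)]
        visits += [_visit("A", t, state="OFF") for t in (0, 1, 2)]
        visits += [_visit("B", 0), _visit("B", 1), _visit("B", 2, state="OFF")]
        slopes = fit_slopes(visits)
        assert list(slopes.values.index) == ["A"]


class TestSubscores:
    def test_all_zero_and_partition(self):
        v = _visit("S", 0.0, fill=0.0)
        out = group_updrs_subscores(v)
        assert out == {"tremor": 0, "bradykinesia": 0, "rigidity": 0,
                       "axial": 0, "total": 0}

    def test_all_ones_partition_sums_to_33(self):
        out = group_updrs_subscores(_visit("S", 0.0, fill=1.0))
        assert out["total"] == 33
        assert out["tremor"] + out["bradykinesia"] + out["rigidity"] + out["axial"] == 33

    def test_partition_property_on_random_visits(self):
        """The four subscores partition the 33 items: they always sum to
        the total."""
        mapping = load_subscore_map()
        items = [i for group in mapping.values() for i in group]
        local = np.random.default_rng(0)
        for _ in range(1000):
            scores = dict(zip(items, local.integers(0, 5, size=33).astype(float)))
            v = VisitRecord("S", 0.0, scores)
            out = group_updrs_subscores(v, mapping)
            subs = out["tremor"] + out["bradykinesia"] + out["rigidity"] + out["axial"]
            assert subs == out["total"]

    def test_missing_item_named_in_error(self):
        v = _visit("S", 0.0)
        del v.items["3.10"]
        v.items["bogus"] = 0.0  # keep the 33-item invariant
        with pytest.raises(KeyError, match="3.10"):
            group_updrs_subscores(v)


class TestLEDD:
    def test_levodopa_and_comt_examples(self):
        levo = [MedicationRecord("s", "levodopa", 100, "mg", 3)]
        assert compute_ledd(levo) == pytest.approx(300.0)
        with_comt = levo + [MedicationRecord("s", "entacapone", 200, "mg", 3)]
        assert compute_ledd(with_comt) == pytest.approx(399.0)

    def test_agonist_factor_and_empty_log(self):
        prami = [MedicationRecord("s", "pramipexole ER", 0.5, "mg", 3)]
        assert compute_ledd(prami) == pytest.approx(0.5 * 3 * 100)
        assert compute_ledd([]) == 0.0

    def test_unknown_unit_rejected(self):
        rec = [MedicationRecord("s", "levodopa", 100, "ml", 3)]
        with pytest.raises(ValueError, match="unit"):
            compute_ledd(rec)

    def test_unknown_drug_skipped(self, caplog):
        rec = [MedicationRecord("s", "aspirin", 100, "mg", 1)]
        assert compute_ledd(rec) == 0.0


class TestALR:
    def test_off_minus_on_sign_convention(self):
        visits = [
            _visit("S", 0.0, fill=30 / 33, state="ON"),
            _visit("S", 0.0, fill=40 / 33, state="OFF"),
            _visit("W", 0.0, fill=32 / 33, state="ON"),
            _visit("W", 0.0, fill=25 / 33, state="OFF"),
            _visit("E", 0.0, fill=1.0, state="ON"),
            _visit("E", 0.0, fill=1.0, state="OFF"),
        ]
        alr = compute_alr(visits).set_index("subject_id")["alr"]
        assert alr["S"] == pytest.approx(10.0)
        assert alr["W"] == pytest.approx(-7.0)  # worsening on drug keeps its sign
        assert alr["E"] == pytest.approx(0.0)

    def test_unpaired_subject_excluded(self):
        visits = [_visit("A", 0.0, state="ON"), _visit("A", 0.0, state="OFF"),
                  _visit("B", 0.0, state="ON")]
        alr = compute_alr(visits)
        assert set(alr["subject_id"]) == {"A"}


class TestFilterAndDummies:
    def test_constant_columns_dropped(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5], "c": [0, 1, 0]})
        out, kept = filter_nonvariable(df)
        assert kept == ["a", "c"]
        assert out.shape == (3, 2)

    def test_drug_dummies_appended_and_validated(self):
        cov = pd.DataFrame({"age": [60.0, 70, 65]}, index=["a", "b", "c"])
        flags = pd.DataFrame(
            {"statin": [0, 1, 0], "antidiabetic": [0, 0, 0], "nsaid": [1, 0, 1]},
            index=["a", "b", "c"])
        out = add_drug_dummies(cov, flags)
        # the all-zero column is dropped; the two informative flags remain
        assert list(out.columns) == ["age", "statin", "nsaid"]
        with pytest.raises(ValueError, match="binary"):
            add_drug_dummies(cov, flags.replace({1: 2}))
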