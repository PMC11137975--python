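import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.feature_selection import f_classif

from mfpinc.feature_selection import (SelectionResult, apply_selection,
                                      f_test_scores, select_pinc10,
                                      variance_above_mean)


def planted_table(n=500, n_features=91, n_informative=10, delta=1.5, seed=5):
    """n x n_features table where the first n_informative columns carry a
    class mean shift of delta; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["ncRNA", "mRNA"])[rng.integers(0, 2, size=n)]
    X = rng.normal(size=(n, n_features))
    X[y == "ncRNA", :n_informative] += delta
    cols = [f"f{i:02d}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), pd.Series(y), cols[:n_informative]


class TestVarianceAboveMean:
    def test_hand_computed_threshold(self):
        # two rows {0, a}: sample variance a^2/2; variances 1, 2, 3, 10
        table = pd.DataFrame({
            "a": [0, np.sqrt(2)], "b": [0, 2.0],
            "c": [0, np.sqrt(6)], "d": [0, np.sqrt(20)],
        })
        assert variance_above_mean(table).selected_names == ["d"]

    def test_equal_variances_select_nothing(self):
        table = pd.DataFrame({"a": [0, 1.0], "b": [2, 3.0], "c": [5, 6.0]})
        assert variance_above_mean(table).selected_names == []

    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"const": np.ones(20),
                              "x": rng.normal(size=20)})
        assert "const" not in variance_above_mean(table).selected_names

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            variance_above_mean(pd.DataFrame({"a": [1.0]}))


class TestFTest:
    def test_class_indicator_gives_infinity(self):
        y = pd.Series(["ncRNA"] * 5 + ["mRNA"] * 5)
        table = pd.DataFrame({"ind": [1.0] * 5 + [0.0] * 5})
        assert f_test_scores(table, y)["ind"] == np.inf

    def test_constant_feature_gives_zero(self):
        y = pd.Series(["ncRNA"] * 5 + ["mRNA"] * 5)
        table = pd.DataFrame({"const": np.ones(10)})
        assert f_test_scores(table, y)["const"] == 0.0

    def test_equals_squared_pooled_t(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(3, 30, size=2)
            x = rng.normal(size=n1 + n2)
            y = np.array(["ncRNA"] * n1 + ["mRNA"] * n2)
            f = f_test_scores(pd.DataFrame({"x": x}), y)["x"]
            t = stats.ttest_ind(x[:n1], x[n1:], equal_var=True).statistic
            assert f == pytest.approx(t ** 2, rel=1e-9)

    def test_matches_sklearn_f_classif(self):
        table, y, _ = planted_table(n=100, n_features=20)
        ours = f_test_scores(table, y)
        theirs, _ = f_classif(table.to_numpy(), y.to_numpy())
        assert np.allclose([ours[c] for c in table.columns], theirs)

    def test_shift_and_scale_invariance(self):
        table, y, _ = planted_table(n=80, n_features=5)
        base = f_test_scores(table, y)
        shifted = f_test_scores(table + 7.0, y)
        scaled = f_test_scores(table * 3.5, y)
        for c in table.columns:
            assert base[c] == pytest.approx(shifted[c], rel=1e-8)
            assert base[c] == pytest.approx(scaled[c], rel=1e-8)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            f_test_scores(pd.DataFrame({"x": np.ones(4)}),
                          pd.Series(["ncRNA"] * 4))


class TestSelectPinc10:
    def test_returns_exactly_k_within_variance_survivors(self):
        table, y, _ = planted_table()
        sel = select_pinc10(table, y)
        survivors = set(variance_above_mean(table).selected_names)
        assert len(sel.selected_names) == 10
        assert set(sel.selected_names) <= survivors

    def test_recovers_planted_features(self):
        table, y, informative = planted_table(n=500, seed=5)
        sel = select_pinc10(table, y)
        assert len(set(sel.selected_names) & set(informative)) >= 8

    def test_deterministic(self):
        table, y, _ = planted_table()
        assert select_pinc10(table, y).selected_names == \
            select_pinc10(table, y).selected_names

    def test_too_few_survivors_reports_count(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"a": rng.normal(size=20),
                              "b": rng.normal(size=20) * 5})
        y = pd.Series(["ncRNA", "mRNA"] * 10)
        with pytest.raises(ValueError, match=r"\d+ features survive"):
            select_pinc10(table, y, k=10)

    def test_json_roundtrip(self, tmp_path):
        table, y, _ = planted_table()
        sel = select_pinc10(table, y)
        sel.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(tmp_path / "sel.json")
        assert back.selected_names == sel.selected_names
        assert back.method == sel.method


class TestApplySelection:
    def test_restricts_and_orders_columns(self):
        table, y, _ = planted_table(n=50, n_features=12)
        sel = SelectionResult("pinc_combined", ["f03", "f00", "f07"])
        reduced = apply_selection(table, sel)
        assert list(reduced.columns) == ["f03", "f00", "f07"]
        assert len(reduced) == 50

    def test_empty_selection_keeps_rows(self):
        table, _, _ = planted_table(n=30, n_features=4)
        reduced = apply_selection(table, SelectionResult("pinc_combined", []))
        assert reduced.shape == (30, 0)

    def test_missing_column_named(self):
        table, _, _ = planted_table(n=30, n_features=4)
        with pytest.raises(KeyError, match="nope"):
            apply_selection(table, SelectionResult("pinc_combined", ["nope"]))
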