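"""Evaluation instruments: std, Pearson, top-5 selection and regression."""

import numpy as np
import pandas as pd
import pytest

from leaflux.evaluation import (
    CorrelationError,
    RegressionError,
    correlation_report,
    compare_methods,
    cv_percent,
    fit_top5_regression,
    pearson,
    select_feasible_top5,
    select_top5,
    vi_std,
)
from leaflux.indices import VI_CODES


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)

    def test_constant_vector_undefined(self):
        with pytest.raises(CorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        p = pearson(x, y)
        assert pearson(3 * x + 7, 0.5 * y - 2) == pytest.approx(p)
        assert pearson(-x, y) == pytest.approx(-p)

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


def _table(values: dict, condition="sunny", method="scaling", n=None) -> pd.DataFrame:
    """Build a minimal VI table; `values` maps code -> per-plant vector."""
    n = n if n is not None else len(next(iter(values.values())))
    base = {code: np.zeros(n) + 0.1 * i for i, code in enumerate(VI_CODES)}
    rng = np.random.default_rng(0)
    for code in VI_CODES:
        base[code] = base[code] + rng.normal(0, 1e-3, n)  # avoid constants
    base.update({k: np.asarray(v, float) for k, v in values.items()})
    df = pd.DataFrame(base)
    df.insert(0, "plant_id", np.arange(1, n + 1))
    df.insert(1, "condition", condition)
    df.insert(2, "method", method)
    return df


def _spad(values) -> pd.DataFrame:
    return pd.DataFrame(
        {"plant_id": np.arange(1, len(values) + 1), "spad": values}
    )


class TestViStd:
    def test_hand_value_and_shift_invariance(self):
        t = _table({"E1": [0.0, 2.0] + [1.0] * 0})
        out = vi_std(t)
        e1 = out[(out.vi == "E1")]["std"].iloc[0]
        assert e1 == pytest.approx(np.sqrt(2.0))
        t2 = _table({"E1": [5.0, 7.0]})
        out2 = vi_std(t2)
        assert out2[(out2.vi == "E1")]["std"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_identical_values_zero(self):
        t = _table({}, n=5)
        t["E1"] = 0.5
        out = vi_std(t)
        assert out[out.vi == "E1"]["std"].iloc[0] == pytest.approx(0.0)

    def test_single_value_missing_with_warning(self, caplog):
        t = _table({"E1": [1.0, 2.0]})
        t.loc[1, "E1"] = np.nan
        out = vi_std(t)
        assert np.isnan(out[out.vi == "E1"]["std"].iloc[0])


class TestCvPercent:
    def test_definition(self):
        assert cv_percent(50.0, 5.0) == pytest.approx(10.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)


class TestSelection:
    def _corr(self, abs_values: dict) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": "scaling",
                    "condition": "sunny",
                    "vi": k,
                    "pearson": v,
                    "abs_pearson": abs(v),
                    "n": 12,
                }
                for k, v in abs_values.items()
            ]
        )

    def test_ordered_case(self):
        corr = self._corr(
            {"E1": 0.9, "E2": 0.8, "E3": 0.7, "E4": 0.6, "E5": 0.5, "E6": 0.1}
        )
        assert select_top5(corr, "scaling", "sunny") == ["E1", "E2", "E3", "E4", "E5"]

    def test_tie_break_by_index_order(self):
        corr = self._corr({c: 0.5 for c in VI_CODES})
        assert select_top5(corr, "scaling", "sunny") == ["E1", "E2", "E3", "E4", "E5"]

    def test_too_few_defined(self):
        corr = self._corr({"E1": 0.9, "E2": 0.8, "E3": 0.7, "E4": 0.6})
        with pytest.raises(RegressionError):
            select_top5(corr, "scaling", "sunny")

    def test_feasible_selection_skips_exact_combinations(self):
        """EXGR = EXG - EXR identically, so a naive top-5 of {E1, E2, E4,..}
        is rank-deficient; the feasible selector must skip one of them."""
        rng = np.random.default_rng(10)
        n = 12
        e1 = rng.normal(0, 1, n)
        e2 = rng.normal(0, 1, n)
        t = _table({"E1": e1, "E2": e2, "E4": e1 - e2})
        y = e1 + 0.5 * e2 + rng.normal(0, 0.1, n)
        corr = correlation_report(t, _spad(y))
        # force E1, E2, E4 to the top of the ranking
        corr.loc[corr.vi.isin(["E1", "E2", "E4"]), "abs_pearson"] = 0.99
        sel = select_feasible_top5(corr, t, "scaling", "sunny")
        assert len(sel) == 5
        assert not {"E1", "E2", "E4"} <= set(sel)


class TestRegression:
    def test_exact_affine_r2_one(self):
        rng = np.random.default_rng(11)
        n = 12
        e1 = rng.normal(0, 1, n)
        t = _table({"E1": e1})
        y = 3 * e1 + 47
        model = fit_top5_regression(t, _spad(y), ["E1", "E2", "E3", "E5", "E6"])
        assert model.r2 == pytest.approx(1.0)

    def test_null_regression_r2_near_p_over_n(self):
        """With pure noise the expected in-sample R2 is p/(n-1): about 0.005
        for five predictors and a thousand samples."""
        rng = np.random.default_rng(12)
        n = 1000
        t = _table({c: rng.normal(0, 1, n) for c in VI_CODES})
        y = rng.normal(0, 1, n)
        model = fit_top5_regression(t, _spad(y), ["E1", "E2", "E3", "E4", "E5"])
        assert model.r2 < 0.05

    def test_r2_equals_one_minus_sse_over_sst(self):
        rng = np.random.default_rng(13)
        n = 30
        cols = {c: rng.normal(0, 1, n) for c in ("E1", "E2", "E3", "E5", "E6")}
        t = _table(cols)
        y = cols["E1"] - cols["E2"] + rng.normal(0, 0.5, n)
        sel = ["E1", "E2", "E3", "E5", "E6"]
        model = fit_top5_regression(t, _spad(y), sel)
        x = np.column_stack([np.ones(n)] + [cols[c] for c in sel])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        sse = np.sum((y - x @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert model.r2 == pytest.approx(1 - sse / sst, abs=1e-9)

    def test_small_n_rejected(self):
        t = _table({"E1": np.arange(6.0)})
        with pytest.raises(RegressionError):
            fit_top5_regression(t, _spad(np.arange(6.0)), list(VI_CODES[:5]))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(14)
        n = 12
        e1, e2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        t = _table({"E1": e1, "E2": e2, "E4": e1 - e2})
        with pytest.raises(RegressionError, match="collinear"):
            fit_top5_regression(
                t, _spad(rng.normal(0, 1, n)), ["E1", "E2", "E4", "E5", "E6"]
            )


class TestCompareMethods:
    def _multi_table(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 12
        signal = rng.normal(0, 1, n)
        frames = []
        for method in ("scaling", "normalized", "elm", "retinex"):
            for condition in ("sunny", "overcast", "variable"):
                if method == "elm" and condition == "variable":
                    continue
                cols = {
                    c: signal * (0.5 + 0.1 * i) + rng.normal(0, 0.3, n)
                    for i, c in enumerate(VI_CODES)
                }
                frames.append(_table(cols, condition=condition, method=method))
        return pd.concat(frames, ignore_index=True), _spad(47 + 3 * signal)

    def test_elm_variable_cell_structurally_absent(self):
        table, spad = self._multi_table()
        report = compare_methods(table, spad)
        assert np.isnan(report.r2_grid.loc["elm", "variable"])
        assert np.isfinite(report.r2_grid.loc["elm", "sunny"])
        assert np.isfinite(report.r2_grid.loc["retinex", "variable"])

    def test_cive_constant_does_not_change_reports(self):
        """Std and Pearson are shift-invariant: removing CIVE's 18.78745
        offset must leave every evaluation output unchanged."""
        table, spad = self._multi_table(seed=5)
        shifted = table.copy()
        shifted["E6"] = shifted["E6"] - 18.78745
        a, b = compare_methods(table, spad), compare_methods(shifted, spad)
        pd.testing.assert_frame_equal(a.std_report, b.std_report)
        pd.testing.assert_frame_equal(a.corr_report, b.corr_report)
        pd.testing.assert_frame_equal(a.r2_grid, b.r2_grid)

    def test_loo_r2_below_in_sample(self):
        table, spad = self._multi_table(seed=6)
        report = compare_methods(table, spad)
        assert (
            report.loo_r2_grid.loc["scaling", "sunny"]
            <= report.r2_grid.loc["scaling", "sunny"]
        )
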