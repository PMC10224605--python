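"""Evaluation of VI consistency and SPAD prediction.

Three instruments compare value conventions (scaling, normalization, ELM,
Retinex) across illumination conditions:

* per-condition standard deviation of each VI over the sampled plants —
  a well-corrected VI should disperse similarly under every sky;
* Pearson correlation of each VI with the SPAD chlorophyll readings;
* an ordinary least-squares regression of SPAD on the five VIs with the
  highest absolute correlation (five predictors to limit overfitting at
  small n), summarized by the coefficient of determination R².

R² is computed as the squared Pearson correlation of observed and fitted
values, which for OLS with an intercept equals 1 - SSE/SST.  Fits are
in-sample, matching a small-plot agronomic protocol; a leave-one-out R² is
reported alongside as a clearly separated extra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .indices import VI_CODES
from .scene import GroundTruthSPAD

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationError",
    "RegressionError",
    "RegressionModel",
    "EvaluationReport",
    "pearson",
    "vi_std",
    "correlation_report",
    "select_top5",
    "select_feasible_top5",
    "fit_top5_regression",
    "compare_methods",
    "cv_percent",
]

N_SELECTED = 5
MIN_N_CORR = 3
CONDITION_NUMBER_LIMIT = 1e8


class CorrelationError(ValueError):
    """Raised when a Pearson correlation is undefined (constant input)."""


class RegressionError(ValueError):
    """Raised for infeasible or collinear top-5 regressions."""


def pearson(x, y) -> float:
    """Pearson correlation: sum of centred cross-products over the product
    of centred norms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < MIN_N_CORR:
        raise ValueError(f"need at least {MIN_N_CORR} observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sum(dx * dx)
    sy = np.sum(dy * dy)
    if sx == 0 or sy == 0:
        raise CorrelationError("correlation undefined for a constant vector")
    return float(np.sum(dx * dy) / np.sqrt(sx * sy))


def cv_percent(mean: float, std: float) -> float:
    """Coefficient of variation in percent, 100 * std / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * std / mean


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ("plant_id", "condition", "method", *VI_CODES) if c not in table]
    if missing:
        raise ValueError(f"VI table missing columns: {missing}")


def vi_std(table: pd.DataFrame) -> pd.DataFrame:
    """Sample standard deviation (n-1 denominator) of each VI per
    (method, condition); fewer than two finite values yields NaN with a
    warning."""
    _check_table(table)
    recs = []
    for (method, condition), grp in table.groupby(["method", "condition"], sort=True):
        for code in VI_CODES:
            vals = grp[code].dropna()
            if len(vals) < 2:
                logger.warning(
                    "std undefined for %s/%s/%s (n=%d)", method, condition, code, len(vals)
                )
                sd = np.nan
            else:
                sd = float(vals.std(ddof=1))
            recs.append(
                {"method": method, "condition": condition, "vi": code, "std": sd,
                 "n": int(len(vals))}
            )
    return pd.DataFrame(recs)


def _spad_series(spad: list[GroundTruthSPAD] | pd.DataFrame) -> pd.Series:
    if isinstance(spad, pd.DataFrame):
        return spad.set_index("plant_id")["spad"].astype(float)
    return pd.Series({s.plant_id: s.spad for s in spad}, dtype=float)


def correlation_report(
    table: pd.DataFrame, spad: list[GroundTruthSPAD] | pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every VI with SPAD per (method, condition).

    Plants with a missing VI value are dropped pairwise; correlations with
    fewer than three plants or a constant vector are reported as NaN.
    """
    _check_table(table)
    y = _spad_series(spad)
    recs = []
    for (method, condition), grp in table.groupby(["method", "condition"], sort=True):
        g = grp.set_index("plant_id")
        for code in VI_CODES:
            x = g[code].dropna()
            common = x.index.intersection(y.index)
            p = np.nan
            if len(common) >= MIN_N_CORR:
                try:
                    p = pearson(x.loc[common].to_numpy(), y.loc[common].to_numpy())
                except CorrelationError:
                    logger.warning(
                        "constant VI %s for %s/%s", code, method, condition
                    )
            recs.append(
                {
                    "method": method,
                    "condition": condition,
                    "vi": code,
                    "pearson": p,
                    "abs_pearson": abs(p) if np.isfinite(p) else np.nan,
                    "n": int(len(common)),
                }
            )
    return pd.DataFrame(recs)


def select_top5(
    corr: pd.DataFrame, method: str, condition: str, k: int = N_SELECTED
) -> list[str]:
    """The k VIs with the largest absolute correlation, ties broken by
    index order (E1 before E2, ...)."""
    sub = corr[(corr["method"] == method) & (corr["condition"] == condition)]
    sub = sub.dropna(subset=["abs_pearson"])
    if len(sub) < k:
        raise RegressionError(
            f"only {len(sub)} defined correlations for {method}/{condition}; need {k}"
        )
    order = {c: i for i, c in enumerate(VI_CODES)}
    ranked = sorted(
        sub.itertuples(index=False), key=lambda r: (-r.abs_pearson, order[r.vi])
    )
    return [r.vi for r in ranked[:k]]


def _standardized_cond(x: np.ndarray) -> float:
    """Condition number of the column-standardized design (with intercept).

    Standardizing removes the arbitrary scale differences between indices
    (CIVE sits near 18.8 with tiny variance) so the number measures actual
    collinearity, not units.
    """
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        return np.inf
    z = (x - x.mean(axis=0)) / sd
    return float(np.linalg.cond(np.column_stack([np.ones(len(z)), z])))


def select_feasible_top5(
    corr: pd.DataFrame,
    table: pd.DataFrame,
    method: str,
    condition: str,
    k: int = N_SELECTED,
) -> list[str]:
    """Greedy top-|P| selection that keeps the design numerically full rank.

    Candidates are visited in decreasing absolute correlation (ties by
    index order); one is skipped when adding it would push the standardized
    design's condition number past the collinearity limit — several indices
    are exact linear combinations of others (e.g. EXGR = EXG - EXR), and on
    chromaticity inputs all difference indices span only two dimensions.
    """
    sub = corr[(corr["method"] == method) & (corr["condition"] == condition)]
    sub = sub.dropna(subset=["abs_pearson"])
    order = {c: i for i, c in enumerate(VI_CODES)}
    ranked = sorted(
        sub.itertuples(index=False), key=lambda r: (-r.abs_pearson, order[r.vi])
    )
    cell = table[(table["method"] == method) & (table["condition"] == condition)]
    chosen: list[str] = []
    for r in ranked:
        trial = chosen + [r.vi]
        x = cell[trial].dropna().to_numpy()
        if x.shape[0] <= len(trial):
            continue
        if _standardized_cond(x) > CONDITION_NUMBER_LIMIT:
            continue
        chosen = trial
        if len(chosen) == k:
            return chosen
    raise RegressionError(
        f"could not assemble {k} non-collinear VIs for {method}/{condition}"
    )


@dataclass(frozen=True)
class RegressionModel:
    """OLS model of SPAD on the selected VIs, with in-sample and LOO R²."""

    selected_vis: tuple[str, ...]
    coefficients: np.ndarray  # intercept followed by slopes
    r2: float
    loo_r2: float
    n: int


def fit_top5_regression(
    table: pd.DataFrame,
    spad: list[GroundTruthSPAD] | pd.DataFrame,
    selection: list[str],
    method: str | None = None,
    condition: str | None = None,
) -> RegressionModel:
    """OLS with intercept of SPAD on the selected VIs.

    R² is the squared Pearson correlation of (y, y-hat), identical to
    1 - SSE/SST for OLS with intercept.  Raises on n <= 6 or a design whose
    condition number exceeds 1e8 (naming the offending VIs).
    """
    _check_table(table)
    sub = table
    if method is not None:
        sub = sub[sub["method"] == method]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    g = sub.set_index("plant_id")[list(selection)].dropna()
    y_all = _spad_series(spad)
    common = g.index.intersection(y_all.index)
    n = len(common)
    if n <= len(selection) + 1:
        raise RegressionError(f"n={n} too small for {len(selection)} predictors")
    x = g.loc[common].to_numpy()
    y = y_all.loc[common].to_numpy()
    design = sm.add_constant(x)
    if _standardized_cond(x) > CONDITION_NUMBER_LIMIT:
        raise RegressionError(f"collinear design among VIs {list(selection)}")
    fit = sm.OLS(y, design).fit()
    yhat = fit.fittedvalues
    r2 = pearson(y, yhat) ** 2
    # leave-one-out via the hat matrix: e_loo = e / (1 - h)
    h = fit.get_influence().hat_matrix_diag
    e_loo = fit.resid / (1.0 - h)
    sst = np.sum((y - y.mean()) ** 2)
    loo_r2 = 1.0 - float(np.sum(e_loo**2)) / sst
    return RegressionModel(
        selected_vis=tuple(selection),
        coefficients=np.asarray(fit.params),
        r2=float(r2),
        loo_r2=loo_r2,
        n=n,
    )


@dataclass
class EvaluationReport:
    """Bundle of the three instruments across methods and conditions."""

    r2_grid: pd.DataFrame          # index: method, columns: condition
    loo_r2_grid: pd.DataFrame
    std_report: pd.DataFrame
    corr_report: pd.DataFrame
    selections: dict[tuple[str, str], tuple[str, ...]]

    def to_dict(self) -> dict:
        return {
            "r2": {
                m: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for m, row in self.r2_grid.iterrows()
            },
            "loo_r2": {
                m: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for m, row in self.loo_r2_grid.iterrows()
            },
            "selections": {f"{m}/{c}": list(v) for (m, c), v in self.selections.items()},
        }


def compare_methods(
    table: pd.DataFrame,
    spad: list[GroundTruthSPAD] | pd.DataFrame,
    reselect_per_cell: bool = True,
) -> EvaluationReport:
    """R² grid of method x condition plus the std and correlation reports.

    ELM is undefined under variable illumination; that cell (and any other
    absent combination) is reported as NaN rather than an error.  By
    default the top-5 VI selection is re-done per (method, condition); with
    ``reselect_per_cell=False`` a single selection from the first available
    cell is reused everywhere.
    """
    _check_table(table)
    stds = vi_std(table)
    corr = correlation_report(table, spad)
    methods = sorted(table["method"].unique())
    conditions = sorted(table["condition"].unique())
    r2 = pd.DataFrame(index=methods, columns=conditions, dtype=float)
    loo = pd.DataFrame(index=methods, columns=conditions, dtype=float)
    selections: dict[tuple[str, str], tuple[str, ...]] = {}
    fixed: list[str] | None = None
    for m in methods:
        for c in conditions:
            cell = table[(table["method"] == m) & (table["condition"] == c)]
            if cell.empty:
                continue
            try:
                if reselect_per_cell or fixed is None:
                    sel = select_feasible_top5(corr, table, m, c)
                    if not reselect_per_cell:
                        fixed = sel
                else:
                    sel = fixed
                model = fit_top5_regression(table, spad, sel, method=m, condition=c)
            except (RegressionError, CorrelationError) as exc:
                logger.warning("cell %s/%s not evaluated: %s", m, c, exc)
                continue
            r2.loc[m, c] = model.r2
            loo.loc[m, c] = model.loo_r2
            selections[(m, c)] = model.selected_vis
    return EvaluationReport(r2, loo, stds, corr, selections)
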