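"""Group comparisons and Lasso-based models of behavioral outcomes.

Two statistical layers mirror the study's analysis:

* independent two-sample t tests (pooled-variance by default, Welch by
  flag) comparing every normalized EEG feature between experienced and
  novice groups, with no multiplicity correction by default and an
  optional Benjamini-Hochberg flag;
* outcome models built by Pearson screening (p < 0.05) of candidate
  features, L1-penalized (Lasso) selection with the penalty chosen by
  5-fold cross-validated mean squared error, and a naive ordinary
  least-squares refit on the selected variables for coefficients,
  standard errors and R².

The refit p-values ignore the selection step (they are not
selection-adjusted); treat them as descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .features import FeatureTable, parse_feature_name
from .spectral import DEFAULT_REPORT_BANDS


@dataclass
class TestResult:
    """An independent two-sample t test for one feature."""

    feature: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    variant: str


def ttest_from_summary(m1: float, s1: float, n1: int,
                       m2: float, s2: float, n2: int,
                       variant: str = "pooled",
                       feature: str = "") -> TestResult:
    """Two-sided independent t test from summary statistics.

    ``pooled`` uses the equal-variance statistic with df = n1 + n2 - 2;
    ``welch`` uses the unequal-variance statistic with Satterthwaite df.
    Degenerate inputs follow the conventions: both variances zero with
    equal means gives t = 0, p = 1; zero pooled variance with unequal
    means gives p = 0.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if min(s1, s2) < 0:
        raise ValueError("standard deviations must be >= 0")

    diff = m1 - m2
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)

    if se == 0.0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(feature=feature, mean1=m1, sd1=s1, n1=n1,
                      mean2=m2, sd2=s2, n2=n2, t=float(t), df=df, p=p,
                      variant=variant)


def ttest_independent(x, y, variant: str = "pooled",
                      feature: str = "") -> TestResult:
    """Two-sided independent t test from raw values.

    Exactly equals :func:`ttest_from_summary` applied to the two
    samples' own means, SDs (ddof=1) and sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValueError("each group needs >= 2 values")
    return ttest_from_summary(float(x.mean()), float(x.std(ddof=1)), len(x),
                              float(y.mean()), float(y.std(ddof=1)), len(y),
                              variant=variant, feature=feature)


def compare_groups(table: FeatureTable,
                   group_order: tuple[str, str] = ("experienced", "novice"),
                   variant: str = "pooled",
                   alpha: float = 0.05,
                   bh_correction: bool = False,
                   report_bands: tuple[str, ...] = DEFAULT_REPORT_BANDS
                   ) -> pd.DataFrame:
    """Per-feature group comparison over a combined multi-task table.

    Returns one row per feature (task, band, kind, channels, group means
    and SDs, t, df, p, significance flag) restricted to ``report_bands``
    and sorted by task, band and kind.  No multiplicity correction is
    applied unless ``bh_correction`` is set, in which case a ``p_adj``
    column (Benjamini-Hochberg) drives the significance flag.
    """
    g1, g2 = group_order
    idx1 = table.groups == g1
    idx2 = table.groups == g2
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise ValueError("each group needs >= 2 participants")

    rows = []
    for col in table.values.columns:
        meta = parse_feature_name(col)
        if meta["band"] not in report_bands:
            continue
        res = ttest_independent(table.values.loc[idx1, col],
                                table.values.loc[idx2, col],
                                variant=variant, feature=col)
        rows.append({**meta, "feature": col,
                     f"mean_{g1}": res.mean1, f"sd_{g1}": res.sd1,
                     f"mean_{g2}": res.mean2, f"sd_{g2}": res.sd2,
                     "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    task_order = {t: i for i, t in enumerate(("reading", "answer1", "answer2"))}
    band_order = {b: i for i, b in enumerate(
        ("delta", "theta", "alpha", "beta", "gamma"))}
    out = out.sort_values(
        ["task", "band", "kind", "channels"],
        key=lambda s: (s.map(task_order) if s.name == "task"
                       else s.map(band_order) if s.name == "band" else s),
    ).reset_index(drop=True)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def pearson_screen(X: pd.DataFrame, outcome: pd.Series,
                   alpha: float = 0.05) -> list[str]:
    """Features whose Pearson correlation with the outcome has p < alpha.

    Constant features (or a constant outcome) carry no correlation and
    are excluded with a warning.
    """
    y = np.asarray(outcome.loc[X.index], dtype=float)
    if len(y) < 3:
        raise ValueError("Pearson screening needs n >= 3")
    if np.std(y) == 0:
        warnings.warn("outcome is constant; nothing screened in", stacklevel=2)
        return []
    keep: list[str] = []
    n_const = 0
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            n_const += 1
            continue
        _, p = sps.pearsonr(x, y)
        if p < alpha:
            keep.append(col)
    if n_const:
        warnings.warn(f"{n_const} constant feature(s) excluded from screening",
                      stacklevel=2)
    return keep


@dataclass
class LassoCVResult:
    """Cross-validated Lasso selection at the MSE-minimizing penalty."""

    chosen_lambda: float
    selected: list[str]
    coef_std: dict[str, float]      # coefficients on standardized features
    lambda_grid: np.ndarray
    cv_mse: np.ndarray              # mean CV MSE per grid value
    seed: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def default_lambda_grid(X: pd.DataFrame, y: pd.Series, n_lambdas: int = 100,
                        min_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from lambda_max (all-zero solution) downward."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / len(yc)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio),
                       n_lambdas)


def lasso_cv(X: pd.DataFrame, y: pd.Series, folds: int = 5,
             lambda_grid: np.ndarray | None = None,
             seed: int = 0) -> LassoCVResult:
    """Choose the Lasso penalty by minimum mean CV MSE over a grid.

    Features are standardized (zero mean, unit variance) inside each
    training fold before penalization; the selected set is the support
    of the full-data fit at the chosen penalty.  Deterministic for a
    fixed seed.  ``lambda = 0`` entries fall back to ordinary least
    squares.
    """
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y.loc[X.index] if hasattr(y, "loc") else y, dtype=float)
    n = len(ya)
    if n < folds:
        raise ValueError(f"n={n} < folds={folds}")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    order = np.argsort(lambda_grid)[::-1]          # descending for lasso_path
    grid_desc = lambda_grid[order]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(grid_desc))
    for train, test in kf.split(Xa):
        Xt, mu, sd = _standardize(Xa[train])
        yt = ya[train]
        ym = yt.mean()
        Xv = (Xa[test] - mu) / sd
        pos = grid_desc > 0
        coefs = np.zeros((Xa.shape[1], len(grid_desc)))
        if pos.any():
            _, cpos, _ = lasso_path(Xt, yt - ym, alphas=grid_desc[pos])
            coefs[:, pos] = cpos
        if (~pos).any():
            beta, *_ = np.linalg.lstsq(Xt, yt - ym, rcond=None)
            coefs[:, ~pos] = beta[:, None]
        pred = ym + Xv @ coefs                     # (n_test, n_lambda)
        sse += ((pred - ya[test][:, None]) ** 2).sum(axis=0)
    mse_desc = sse / n

    best = int(np.argmin(mse_desc))                # ties -> largest lambda
    lam = float(grid_desc[best])

    Xs, _, _ = _standardize(Xa)
    yc = ya - ya.mean()
    if lam > 0:
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=50000)
        model.fit(Xs, yc)
        beta = model.coef_
    else:
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    selected = [nm for nm, b in zip(names, beta) if b != 0.0]

    # report cv curve in the caller's grid order
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return LassoCVResult(chosen_lambda=lam, selected=selected,
                         coef_std={nm: float(b) for nm, b in zip(names, beta)},
                         lambda_grid=lambda_grid, cv_mse=mse_desc[inv],
                         seed=seed)


@dataclass
class ModelFit:
    """Post-selection OLS refit of an outcome on Lasso-selected features."""

    outcome: str
    selected: list[str]
    intercept: float
    intercept_se: float
    intercept_p: float
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    r2: float = 0.0
    chosen_lambda: float = 0.0
    cv_mse: list[float] = field(default_factory=list)
    lambda_grid: list[float] = field(default_factory=list)
    fold_seed: int = 0
    screened: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "r2": self.r2,
            "intercept": {"coef": self.intercept, "se": self.intercept_se,
                          "p": self.intercept_p},
            "terms": [{"feature": f, "coef": self.coef[f], "se": self.se[f],
                       "p": self.pvalues[f]} for f in self.selected],
            "chosen_lambda": self.chosen_lambda,
            "fold_seed": self.fold_seed,
            "screened": self.screened,
            "lambda_grid": self.lambda_grid,
            "cv_mse": self.cv_mse,
            "note": "standard errors and p-values are a naive OLS refit; "
                    "they are not adjusted for Lasso selection",
        }


def post_lasso_ols(X: pd.DataFrame, y: pd.Series,
                   outcome: str = "outcome") -> ModelFit:
    """Ordinary least-squares refit on the selected columns.

    Reports raw-scale coefficients, their (selection-naive) standard
    errors and p-values, and R².  An empty ``X`` yields the
    intercept-only model with R² = 0.  Aliased (rank-deficient) columns
    are dropped with a warning.
    """
    import statsmodels.api as sm

    ya = y.loc[X.index] if len(X.columns) and len(X) else y
    cols = list(X.columns)
    if cols:
        mat = np.asarray(X, dtype=float)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat]))
        if rank < len(cols) + 1:
            keep: list[str] = []
            base = np.ones((len(mat), 1))
            for i, c in enumerate(cols):
                cand = np.column_stack([base, mat[:, i]])
                if np.linalg.matrix_rank(cand) > base.shape[1]:
                    base = cand
                    keep.append(c)
            dropped = [c for c in cols if c not in keep]
            warnings.warn(f"dropping aliased columns: {dropped}", stacklevel=2)
            cols = keep
    design = sm.add_constant(X[cols] if cols else
                             pd.DataFrame(index=ya.index))
    if design.shape[1] == 0:
        design = pd.DataFrame({"const": np.ones(len(ya))}, index=ya.index)
    fit = sm.OLS(np.asarray(ya, dtype=float), np.asarray(design, float)).fit()
    names = ["const"] + cols
    params = dict(zip(names, fit.params))
    bse = dict(zip(names, fit.bse))
    pvals = dict(zip(names, fit.pvalues))
    r2 = float(fit.rsquared) if cols else 0.0
    return ModelFit(outcome=outcome, selected=cols,
                    intercept=float(params["const"]),
                    intercept_se=float(bse["const"]),
                    intercept_p=float(pvals["const"]),
                    coef={c: float(params[c]) for c in cols},
                    se={c: float(bse[c]) for c in cols},
                    pvalues={c: float(pvals[c]) for c in cols},
                    r2=r2)


def _shrink_to_identifiable(X: pd.DataFrame, y: pd.Series,
                            sel: LassoCVResult, cap: int) -> LassoCVResult:
    """Raise the penalty to the first grid value whose support fits the cap.

    The OLS refit needs residual degrees of freedom; when the CV-chosen
    penalty selects more features than ``n - 3`` we move up the (sorted)
    penalty grid to the smallest lambda whose support is identifiable.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    ya = np.asarray(y.loc[X.index], dtype=float)
    yc = ya - ya.mean()
    names = list(X.columns)
    for lam in np.sort(sel.lambda_grid[sel.lambda_grid >= sel.chosen_lambda]):
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=50000)
        model.fit(Xs, yc)
        support = [nm for nm, b in zip(names, model.coef_) if b != 0.0]
        if len(support) <= cap:
            warnings.warn(
                f"CV-minimum penalty selected {len(sel.selected)} features "
                f"for n={len(ya)}; penalty raised to {lam:.3g} for an "
                "identifiable OLS refit", stacklevel=2)
            return LassoCVResult(
                chosen_lambda=float(lam), selected=support,
                coef_std={nm: float(b) for nm, b in zip(names, model.coef_)},
                lambda_grid=sel.lambda_grid, cv_mse=sel.cv_mse, seed=sel.seed)
    return LassoCVResult(chosen_lambda=float(sel.lambda_grid.max()),
                         selected=[], coef_std={},
                         lambda_grid=sel.lambda_grid, cv_mse=sel.cv_mse,
                         seed=sel.seed)


def fit_outcome_model(table: FeatureTable, outcome: pd.Series,
                      outcome_name: str, folds: int = 5, seed: int = 0,
                      screen_alpha: float = 0.05,
                      lambda_grid: np.ndarray | None = None) -> ModelFit:
    """Screen -> Lasso-CV -> OLS refit, the study's modeling recipe."""
    n_obs = len(table.values)
    if n_obs < folds:
        warnings.warn(f"only {n_obs} observations; reducing CV folds from "
                      f"{folds} to {n_obs}", stacklevel=2)
        folds = n_obs
    screened = pearson_screen(table.values, outcome, alpha=screen_alpha)
    if not screened:
        fit = post_lasso_ols(pd.DataFrame(index=table.values.index), outcome,
                             outcome=outcome_name)
        fit.fold_seed = seed
        return fit
    sel = lasso_cv(table.values[screened], outcome, folds=folds,
                   lambda_grid=lambda_grid, seed=seed)
    cap = max(len(table.values.index) - 3, 1)
    if len(sel.selected) > cap:
        sel = _shrink_to_identifiable(table.values[screened], outcome, sel, cap)
    fit = post_lasso_ols(table.values[sel.selected], outcome,
                         outcome=outcome_name)
    fit.chosen_lambda = sel.chosen_lambda
    fit.cv_mse = [float(v) for v in sel.cv_mse]
    fit.lambda_grid = [float(v) for v in sel.lambda_grid]
    fit.fold_seed = seed
    fit.screened = screened
    return fit
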