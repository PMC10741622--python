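"""Observational checklist scoring, NASA-TLX totals, inter-rater ICC.

Decision-making performance is scored on a weighted checklist whose
items are rated No/Maybe/Yes = 0/1/2; the participant's score is the
weighted percent of the maximum.  Self-reported workload is the NASA
Task Load Index: six 0-20 visual-analog subscales summed to a 0-120
total (raw-sum "RTLX" convention, no pairwise weighting) and rescaled
to a 0-1 fraction.  Agreement between the two independent raters is
quantified with the single-rater, absolute-agreement intraclass
correlation from a two-way random-effects ANOVA — ICC(2,1) — the form
whose F test has (n-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

VALID_RATINGS = (0, 1, 2)


@dataclass
class ChecklistRating:
    """One rater's checklist for one participant: (weight, rating) items."""

    items: list[tuple[float, int]]
    rater: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("checklist needs at least one item")
        for w, r in self.items:
            if w <= 0:
                raise ValueError(f"item weight must be positive, got {w}")
            if r not in VALID_RATINGS:
                raise ValueError(f"rating must be in {VALID_RATINGS}, got {r!r}")


def weighted_percent(rating: ChecklistRating) -> float:
    """Total weighted score over total possible score, in [0, 1]."""
    got = sum(w * r for w, r in rating.items)
    possible = sum(w * 2 for w, _ in rating.items)
    return got / possible


@dataclass
class TLXRating:
    """Six NASA-TLX subscales, each on the 0-20 visual-analog scale."""

    mental: float
    physical: float
    temporal: float
    performance_demand: float
    effort: float
    frustration: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 20.0:
                raise ValueError(f"TLX subscale {name}={v} outside [0, 20]")

    def values(self) -> list[float]:
        return [self.mental, self.physical, self.temporal,
                self.performance_demand, self.effort, self.frustration]


def tlx_total(rating: TLXRating) -> tuple[float, float]:
    """Raw-sum workload total on 0-120 and its 0-1 fraction."""
    total = float(sum(rating.values()))
    return total, total / 120.0


@dataclass
class ICCResult:
    """ICC(2,1) with its F test and 95% confidence interval."""

    icc: float
    f: float
    df1: int
    df2: int
    p: float
    ci_low: float
    ci_high: float
    ms_subjects: float
    ms_raters: float
    ms_error: float


def icc_absolute_agreement(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-rater absolute-agreement ICC from a two-way random model.

    ``ratings`` is a complete subjects x raters matrix (>=2 of each, no
    missing cells).  Mean squares come from the two-way ANOVA
    decomposition; the significance test is F = MS_subjects / MS_error
    with (n-1, (n-1)(k-1)) degrees of freedom, and the confidence
    interval is the standard F-based interval for this ICC form
    (Satterthwaite degrees of freedom for the lower/upper bounds).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >=2 of each")
    if not np.isfinite(x).all():
        raise ValueError("ratings matrix has missing/non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("ICC undefined: no subject variance and no residual "
                         "variance in the ratings matrix")
    icc = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        fstat = msr / mse
        p = float(sps.f.sf(fstat, df1, df2))
    else:
        fstat, p = np.inf, 0.0

    if icc >= 1.0 or mse == 0.0:
        ci_low, ci_high = (icc, 1.0) if icc < 1 else (1.0, 1.0)
    else:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df2))
        f_lo = sps.f.ppf(1 - alpha / 2, df1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, df1)
        ci_low = (n * (msr - f_lo * mse)
                  / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
        ci_high = (n * (f_hi * msr - mse)
                   / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    return ICCResult(icc=float(icc), f=float(fstat), df1=df1, df2=df2, p=p,
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     ms_subjects=float(msr), ms_raters=float(msc),
                     ms_error=float(mse))


def _rater_columns(table: pd.DataFrame, rater: int) -> list[str]:
    cols = [c for c in table.columns if c.startswith(f"rater{rater}_item")]
    if not cols:
        raise ValueError(f"no checklist columns found for rater {rater}")
    return sorted(cols)


def score_behavior(table: pd.DataFrame,
                   weights: np.ndarray | None = None) -> pd.DataFrame:
    """Score a behavioral table (one row per participant).

    Expects the column layout written by the simulator / behavioral CSV:
    ``group``, six ``tlx_*`` subscales and ``rater{1,2}_item*`` checklist
    ratings.  Item weights default to 1.  Returns per-participant scores:
    TLX total and fraction, each rater's weighted percent and their mean.
    """
    tlx_cols = [c for c in table.columns if c.startswith("tlx_")]
    if len(tlx_cols) != 6:
        raise ValueError(f"expected 6 TLX subscale columns, found {len(tlx_cols)}")
    out = pd.DataFrame(index=table.index)
    out["group"] = table["group"]
    totals = table[tlx_cols].sum(axis=1)
    out["tlx_total"] = totals
    out["tlx_fraction"] = totals / 120.0

    for rater in (1, 2):
        cols = _rater_columns(table, rater)
        w = np.ones(len(cols)) if weights is None else np.asarray(weights, float)
        if len(w) != len(cols):
            raise ValueError("weights length does not match item count")
        scores = []
        for pid, row in table[cols].iterrows():
            rating = ChecklistRating(
                items=list(zip(w, (int(v) for v in row))),
                rater=f"rater{rater}", participant=str(pid))
            scores.append(weighted_percent(rating))
        out[f"performance_rater{rater}"] = scores
    out["performance"] = out[["performance_rater1",
                              "performance_rater2"]].mean(axis=1)
    bad_tlx = (table[tlx_cols] < 0).any().any() or (table[tlx_cols] > 20).any().any()
    if bad_tlx:
        warnings.warn("TLX subscale values outside [0, 20] present", stacklevel=2)
    return out


def rater_agreement(scores: pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) of the two raters' weighted performance percents."""
    m = scores[["performance_rater1", "performance_rater2"]].to_numpy()
    return icc_absolute_agreement(m, alpha=alpha)
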