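"""Variant enrichment statistics.

Four estimators cover the common selection designs:

* :func:`ratio_score` — pseudocounted log-ratio between two conditions,
  with a Poisson-approximation standard error, optionally normalised to
  the wild-type row so wt scores exactly 0:

      score_v = ln((c_vT + d)/(c_v0 + d)) - ln((c_wtT + d)/(c_wt0 + d))
      SE_v    = sqrt(1/(c_v0+d) + 1/(c_vT+d) + 1/(c_wt0+d) + 1/(c_wtT+d))

* :func:`regression_score` — weighted least-squares slope of the
  wt-normalised log counts over normalised time x_t in [0, 1]; the slope
  is the total log-enrichment over the experiment.  Weights are the
  count-derived inverse variances, taken as known (no residual
  rescaling).

* :func:`combine_replicates` — DerSimonian–Laird random-effects
  meta-analysis across replicates: a method-of-moments between-replicate
  variance sigma2_s (floored at 0) inflates the per-replicate variances
  before inverse-variance averaging; the heterogeneity statistic Q and
  replicate count are reported alongside.

* :func:`bin_score` — FACS sort-seq score: within-bin frequencies,
  renormalised across bins, averaged with user-supplied bin weights
  (default equally spaced b/B).

The pseudocount d (default 0.5) stabilises zero counts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import Table

__all__ = [
    "CombinedScore",
    "ratio_score",
    "regression_score",
    "combine_replicates",
    "combine_replicates_table",
    "bin_score",
]

DEFAULT_PSEUDOCOUNT = 0.5


def _normalised_times(times: list[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two time values")
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"times must be strictly increasing, got {list(t)}")
    span = t[-1] - t[0]
    if span == 0:
        raise ValueError("all time values identical")
    return (t - t[0]) / span


def _counts_matrix(df: pd.DataFrame, count_cols: list[str]) -> np.ndarray:
    for c in count_cols:
        if c not in df.columns:
            raise ValueError(f"count column {c!r} not in table")
    arr = df[count_cols].to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(arr).any():
        raise ValueError("count columns contain missing values")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _wt_index(df: pd.DataFrame, variant_col: str, wt: str) -> int:
    idx = np.flatnonzero((df[variant_col] == wt).to_numpy(dtype=bool, na_value=False))
    if len(idx) == 0:
        raise ValueError(f"wild-type row {wt!r} not found in column {variant_col!r}")
    if len(idx) > 1:
        raise ValueError(f"multiple wild-type rows {wt!r}")
    return int(idx[0])


def _per_group(df: pd.DataFrame, group_cols: list[str]):
    if not group_cols:
        yield (), df
        return
    for key, sub in df.groupby(group_cols, dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        yield key, sub


def ratio_score(
    table: Table,
    variant_col: str,
    count_cols: list[str],
    wt: str = "c.=",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize_wt: bool = True,
    group_cols: list[str] | None = None,
) -> Table:
    """Log-ratio enrichment score between two conditions.

    ``count_cols`` are (initial, final).  With ``group_cols`` (e.g. a
    replicate column) scoring and wt normalisation are applied within
    each group independently.
    """
    if len(count_cols) != 2:
        raise ValueError("ratio_score requires exactly two count columns (initial, final)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    d = pseudocount
    frames = []
    for _, sub in _per_group(table.df, group_cols or []):
        c = _counts_matrix(sub, count_cols) + d
        score = np.log(c[:, 1]) - np.log(c[:, 0])
        var = 1.0 / c[:, 0] + 1.0 / c[:, 1]
        if normalize_wt:
            i = _wt_index(sub, variant_col, wt)
            score = score - score[i]
            var = var + 1.0 / c[i, 0] + 1.0 / c[i, 1]
        out = sub[[variant_col] + (group_cols or [])].copy()
        out["score"] = pd.array(score, dtype="Float64")
        out["SE"] = pd.array(np.sqrt(var), dtype="Float64")
        frames.append(out)
    res = pd.concat(frames, ignore_index=True)
    res["method"] = pd.array(["ratio"] * len(res), dtype="string")
    return Table(res)


def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted normal equations; weights are known inverse
    variances, so Var(slope) = S_w / (S_w S_wxx - S_wx^2)."""
    sw = w.sum(axis=-1)
    swx = (w * x).sum(axis=-1)
    swy = (w * y).sum(axis=-1)
    swxx = (w * x * x).sum(axis=-1)
    swxy = (w * x * y).sum(axis=-1)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    slope_var = sw / det
    return slope, intercept, slope_var


def regression_score(
    table: Table,
    variant_col: str,
    count_cols: list[str],
    times: list[float] | None = None,
    wt: str = "c.=",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize_wt: bool = True,
    group_cols: list[str] | None = None,
) -> Table:
    """WLS slope of log counts over >= 3 time points.

    x is time normalised to [0, 1], so the slope is the total
    log-enrichment over the experiment; with wt normalisation the wt
    variant's slope is 0 by construction.
    """
    if len(count_cols) < 3:
        raise ValueError(
            "regression_score needs at least 3 time points; use ratio_score for 2"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if times is None:
        times = list(range(len(count_cols)))
    if len(times) != len(count_cols):
        raise ValueError("times must match count columns")
    x = _normalised_times(times)
    d = pseudocount
    frames = []
    for _, sub in _per_group(table.df, group_cols or []):
        c = _counts_matrix(sub, count_cols) + d
        y = np.log(c)
        var = 1.0 / c
        if normalize_wt:
            i = _wt_index(sub, variant_col, wt)
            y = y - y[i]
            var = var + var[i]
        w = 1.0 / var
        slope, intercept, slope_var = _wls_slope(x, y, w)
        out = sub[[variant_col] + (group_cols or [])].copy()
        out["score"] = pd.array(slope, dtype="Float64")
        out["SE"] = pd.array(np.sqrt(slope_var), dtype="Float64")
        out["intercept"] = pd.array(intercept, dtype="Float64")
        frames.append(out)
    res = pd.concat(frames, ignore_index=True)
    res["method"] = pd.array(["regression"] * len(res), dtype="string")
    return Table(res)


@dataclass(frozen=True)
class CombinedScore:
    """Random-effects summary across replicates."""

    score: float
    se: float
    q: float
    sigma2_s: float
    n: int


def combine_replicates(betas, ses) -> CombinedScore:
    """DerSimonian–Laird random-effects combination of per-replicate
    (score, SE) pairs; requires n >= 2 and positive SEs."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be equal-length 1-d sequences")
    n = len(b)
    if n < 2:
        raise ValueError("replicate combination requires at least 2 replicates")
    if np.any(s <= 0) or not np.all(np.isfinite(s)) or not np.all(np.isfinite(b)):
        raise ValueError("all standard errors must be finite and > 0")
    w = 1.0 / s**2
    ybar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - ybar) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    sigma2 = max(0.0, (q - (n - 1)) / denom)
    wstar = 1.0 / (s**2 + sigma2)
    beta = float(np.sum(wstar * b) / np.sum(wstar))
    se = float(np.sqrt(1.0 / np.sum(wstar)))
    return CombinedScore(beta, se, q, sigma2, n)


def combine_replicates_table(
    table: Table,
    variant_col: str,
    score_col: str = "score",
    se_col: str = "SE",
) -> Table:
    """Combine per-replicate score rows into one row per variant.

    Rows with a missing score or SE are dropped before combination;
    variants left with a single replicate keep that replicate's values
    with sigma2_s/Q missing and n = 1.
    """
    for c in (variant_col, score_col, se_col):
        if c not in table.columns:
            raise ValueError(f"column {c!r} not in table")
    df = table.df
    rows = []
    for key, sub in df.groupby(variant_col, dropna=False, sort=True):
        ok = sub[[score_col, se_col]].notna().all(axis=1)
        sub = sub[ok]
        if len(sub) == 0:
            rows.append((key, None, None, None, None, 0))
        elif len(sub) == 1:
            rows.append(
                (key, float(sub[score_col].iloc[0]), float(sub[se_col].iloc[0]), None, None, 1)
            )
        else:
            c = combine_replicates(
                sub[score_col].to_numpy(dtype=float), sub[se_col].to_numpy(dtype=float)
            )
            rows.append((key, c.score, c.se, c.q, c.sigma2_s, c.n))
    out = pd.DataFrame(
        rows, columns=[variant_col, "score", "SE", "Q", "sigma2_s", "n_reps"]
    )
    out["n_reps"] = out["n_reps"].astype("Int64")
    out["method"] = pd.array(["random_effects"] * len(out), dtype="string")
    return Table(out)


def bin_score(
    table: Table,
    variant_col: str,
    count_cols: list[str],
    weights: list[float] | None = None,
    min_total_count: int = 0,
    cell_fractions: list[float] | None = None,
) -> Table:
    """Weighted-average FACS bin score.

    Within-bin variant frequencies f_vb are optionally rescaled by
    per-bin sorted-cell fractions, renormalised across bins to F_vb, and
    averaged with the bin weights: score_v = sum_b w_b F_vb.  Variants
    below ``min_total_count`` total reads get a missing score and a
    low_count flag; no analytic SE is emitted (replicate combination
    supplies spread).
    """
    b = len(count_cols)
    if b < 2:
        raise ValueError("bin scoring requires at least 2 bins")
    if weights is None:
        weights = [(i + 1) / b for i in range(b)]
    if len(weights) != b:
        raise ValueError("weights must match bins")
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("bin weights must be finite")
    if cell_fractions is None:
        cf = np.ones(b)
    else:
        cf = np.asarray(cell_fractions, dtype=float)
        if len(cf) != b or np.any(cf <= 0):
            raise ValueError("cell_fractions must be positive, one per bin")
    df = table.df
    counts = _counts_matrix(df, count_cols)
    totals = counts.sum(axis=0)
    used = counts.sum(axis=0) > 0
    for j in range(b):
        if totals[j] == 0 and counts[:, j].sum() > 0:  # pragma: no cover - defensive
            raise ValueError(f"bin {count_cols[j]} total is zero but holds counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
        f = f * cf
        row_sum = f.sum(axis=1)
        big_f = np.where(row_sum[:, None] > 0, f / np.where(row_sum[:, None] > 0, row_sum[:, None], 1.0), np.nan)
        score = (big_f * w).sum(axis=1)
    variant_total = counts.sum(axis=1)
    low = variant_total < min_total_count
    absent = row_sum == 0
    score = np.where(low | absent, np.nan, score)
    out = df[[variant_col]].copy()
    out["score"] = pd.array([None if np.isnan(v) else v for v in score], dtype="Float64")
    out["SE"] = pd.array([None] * len(out), dtype="Float64")
    out["total_count"] = pd.array(variant_total.astype(int), dtype="Int64")
    out["low_count"] = pd.array(low.tolist(), dtype="boolean")
    out["method"] = pd.array(["bin_weighted"] * len(out), dtype="string")
    return Table(out)
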