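"""Behavioral, functional, and structural properties of reliable edges.

Given the consistency classification of the selected parcel edges (pooled
over frequency bands and time windows), this module asks what
distinguishes consistent from inconsistent edges:

* a per-edge multiple regression of the mean-over-sessions summed contrast
  on the three language scores (overall F-test at 0.05, deliberately
  uncorrected for multiplicity — the comparison between groups is of
  *rates* of nominal fits);
* chi-square tests of independence (consistency × regression fit;
  laterality × modulation direction), with the Yates continuity correction
  applied automatically to 2×2 tables only;
* two-sided Mann-Whitney U comparisons of absolute connectivity strength
  and of the structural profile metrics (direct streamlines, shortest path
  length, edge betweenness).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import BEHAVIOR_COLUMNS, Parcellation, validate_behavior
from .selection import ParcelEdge

logger = logging.getLogger(__name__)

FIT_ALPHA = 0.05


@dataclass
class EdgeBehaviorResult:
    edge: ParcelEdge | None
    F: float
    p: float
    fitted: bool  # p < 0.05


@dataclass
class ComparisonResult:
    kind: str  # 'chi2' | 'mannwhitneyU'
    statistic: float
    p: float
    df: int | None = None
    group_summaries: dict = field(default_factory=dict)
    continuity_correction: bool = False


def behavior_association(
    edge_series_mean: np.ndarray,
    behavior: pd.DataFrame,
    edge: ParcelEdge | None = None,
) -> EdgeBehaviorResult:
    """OLS of the per-subject mean contrast on the three language scores.

    ``edge_series_mean`` is the per-subject contrast averaged over the two
    sessions.  The overall model F-test has (3, n−4) degrees of freedom;
    ``fitted`` means p < 0.05.
    """
    validate_behavior(behavior)
    y = np.asarray(edge_series_mean, dtype=float)
    X = behavior[list(BEHAVIOR_COLUMNS)].to_numpy(dtype=float)
    n = len(y)
    if n != len(X):
        raise ValueError("edge series and behavior table must cover the same subjects")
    if n < 6:
        raise ValueError("need at least 6 subjects for the 3-predictor regression")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"collinear behavioral predictors: {bad}")
    fit = sm.OLS(y, Xc).fit()
    p = float(fit.f_pvalue)
    return EdgeBehaviorResult(edge=edge, F=float(fit.fvalue), p=p, fitted=p < FIT_ALPHA)


def _collinear_columns(X: np.ndarray) -> list[str]:
    cols = list(BEHAVIOR_COLUMNS)
    bad = []
    for i in range(X.shape[1]):
        others = np.delete(X, i, axis=1)
        proj = np.linalg.lstsq(np.column_stack([np.ones(len(X)), others]), X[:, i], rcond=None)
        resid = X[:, i] - np.column_stack([np.ones(len(X)), others]) @ proj[0]
        if np.allclose(resid, 0):
            bad.append(cols[i])
    return bad or cols


def behavior_screen_many(Y: np.ndarray, behavior: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized overall-F screen for many edges at once.

    ``Y`` has shape (n_edges, n_subjects).  Returns (F, p) arrays; agrees
    with :func:`behavior_association` edge by edge.  Used for calibration
    studies where fitting thousands of separate models matters.
    """
    validate_behavior(behavior)
    X = behavior[list(BEHAVIOR_COLUMNS)].to_numpy(dtype=float)
    n = X.shape[0]
    q = X.shape[1]
    Y = np.asarray(Y, dtype=float)
    Xc = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xc, Y.T, rcond=None)
    resid = Y.T - Xc @ coef
    rss = (resid**2).sum(axis=0)
    tss = ((Y.T - Y.T.mean(axis=0)) ** 2).sum(axis=0)
    df_model, df_resid = q, n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / df_model) / (rss / df_resid)
    p = stats.f.sf(F, df_model, df_resid)
    return F, p


def chi2_independence(table: np.ndarray, continuity: str = "auto") -> ComparisonResult:
    """Pearson chi-square test of independence for an r×c count table.

    ``continuity`` is 'auto' (Yates iff the table is 2×2), 'on', or 'off'.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    if continuity == "auto":
        correction = t.shape == (2, 2)
    elif continuity in ("on", "off"):
        correction = continuity == "on"
    else:
        raise ValueError("continuity must be 'auto', 'on' or 'off'")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return ComparisonResult(
        kind="chi2",
        statistic=float(chi2),
        p=float(p),
        df=int(df),
        group_summaries={"counts": t.astype(int).tolist(), "N": int(t.sum())},
        continuity_correction=bool(correction),
    )


def mwu_compare(values_a, values_b) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two groups.

    Exact enumeration when both groups have <= 20 observations and there
    are no ties; tie-corrected normal approximation otherwise.  The
    reported U is the statistic of group A.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        kind="mannwhitneyU",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        group_summaries={
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "n_a": len(a),
            "n_b": len(b),
            "method": method,
        },
    )


def mwu_exact_enumeration(values_a, values_b) -> tuple[float, float]:
    """Brute-force exact two-sided Mann-Whitney p by full enumeration.

    Enumerates all assignments of the pooled sample into the two group
    sizes; p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  Only sensible for
    small groups; exposed for validation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    na = len(a)
    u_obs = _u_statistic(a, b)
    us = [
        _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
        for idx in itertools.combinations(range(len(pooled)), na)
    ]
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def strength_summary(series: np.ndarray) -> float:
    """Absolute mean connectivity strength of one parcel edge.

    The mean over subjects and both sessions of the summed contrast is
    taken first; the absolute value is applied *after* averaging.
    """
    x = np.asarray(series, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return float(abs(x.mean()))


def laterality(edge: ParcelEdge, parcellation: Parcellation) -> str:
    """'left', 'right' (both parcels in that hemisphere) or 'bilateral'."""
    ha = parcellation.hemisphere_of(edge.parcel_a)
    hb = parcellation.hemisphere_of(edge.parcel_b)
    if ha == hb:
        return ha
    return "bilateral"


def reconstruct_counts(
    total: int,
    pct_group1: float,
    pct_hit_group1: float,
    pct_hit_group2: float,
    decimals: int = 1,
) -> np.ndarray:
    """Reconstruct a 2×2 count table from a total and printed percentages.

    Finds the integer split (group sizes from ``pct_group1`` of ``total``;
    within-group hit counts from the two hit percentages) whose percentages
    round to the printed values at ``decimals`` places.  Raises if no
    solution or several distinct solutions exist.
    """

    def _matches(count: int, denom: int, pct: float) -> bool:
        return denom > 0 and round(100.0 * count / denom, decimals) == round(pct, decimals)

    solutions = []
    for n1 in range(total + 1):
        if not _matches(n1, total, pct_group1):
            continue
        n2 = total - n1
        hits1 = [h for h in range(n1 + 1) if _matches(h, n1, pct_hit_group1)]
        hits2 = [h for h in range(n2 + 1) if _matches(h, n2, pct_hit_group2)]
        for h1 in hits1:
            for h2 in hits2:
                solutions.append([[h1, n1 - h1], [h2, n2 - h2]])
    unique = {tuple(map(tuple, s)) for s in solutions}
    if not unique:
        raise ValueError("no integer table matches the printed percentages")
    if len(unique) > 1:
        raise ValueError(f"ambiguous reconstruction: {sorted(unique)}")
    return np.array(solutions[0], dtype=int)


@dataclass
class PropertyReport:
    """Pooled consistent-vs-inconsistent comparison results."""

    edge_table: pd.DataFrame
    n_consistent: int
    n_inconsistent: int
    consistency_fit_chi2: ComparisonResult | None
    laterality_direction_chi2: ComparisonResult | None
    comparisons: dict  # metric name -> ComparisonResult | None
    notices: list


def property_report(edge_table: pd.DataFrame, continuity: str = "auto") -> PropertyReport:
    """Assemble the consistent-vs-inconsistent property report.

    ``edge_table`` pools all selected parcel edges over bands and windows,
    one row per edge, with columns: ``label`` ('consistent'/'inconsistent'),
    ``fitted`` (bool), ``direction``, ``laterality``, ``strength``, and the
    structural profile columns ``mean_streamlines``, ``mean_spl``,
    ``mean_ebc`` (may be absent if no structural data).
    """
    notices: list[str] = []
    cons = edge_table[edge_table["label"] == "consistent"]
    incons = edge_table[edge_table["label"] == "inconsistent"]

    fit_chi2 = None
    if len(cons) and len(incons):
        table = np.array(
            [
                [int(cons["fitted"].sum()), int((~cons["fitted"].astype(bool)).sum())],
                [int(incons["fitted"].sum()), int((~incons["fitted"].astype(bool)).sum())],
            ]
        )
        try:
            fit_chi2 = chi2_independence(table, continuity)
        except ValueError as exc:
            notices.append(f"consistency x fit chi-square skipped: {exc}")
    else:
        notices.append("consistency x fit chi-square skipped: a consistency group is empty")

    lat_chi2 = None
    lat_order = ["left", "right", "bilateral"]
    if len(cons):
        counts = (
            cons.groupby(["direction", "laterality"]).size().unstack(fill_value=0)
        )
        counts = counts.reindex(index=["increase", "decrease"], columns=lat_order, fill_value=0)
        try:
            lat_chi2 = chi2_independence(counts.to_numpy(), continuity)
        except ValueError as exc:
            notices.append(f"laterality x direction chi-square skipped: {exc}")
    else:
        notices.append("laterality x direction chi-square skipped: no consistent edges")

    comparisons: dict[str, ComparisonResult | None] = {}
    metrics = ["strength"] + [
        c for c in ("mean_streamlines", "mean_spl", "mean_ebc") if c in edge_table.columns
    ]
    for metric in metrics:
        if not (len(cons) and len(incons)):
            comparisons[metric] = None
            notices.append(f"{metric} comparison skipped: a consistency group is empty")
            continue
        va = cons[metric].to_numpy(dtype=float)
        vb = incons[metric].to_numpy(dtype=float)
        n_inf = int(np.isinf(va).sum() + np.isinf(vb).sum())
        if n_inf:
            notices.append(f"{metric}: {n_inf} infinite values excluded from the comparison")
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if len(va) == 0 or len(vb) == 0:
            comparisons[metric] = None
            notices.append(f"{metric} comparison skipped: no finite values in a group")
            continue
        comparisons[metric] = mwu_compare(va, vb)

    for msg in notices:
        logger.info(msg)
    return PropertyReport(
        edge_table=edge_table,
        n_consistent=len(cons),
        n_inconsistent=len(incons),
        consistency_fit_chi2=fit_chi2,
        laterality_direction_chi2=lat_chi2,
        comparisons=comparisons,
        notices=notices,
    )
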