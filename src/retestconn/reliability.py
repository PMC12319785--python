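"""ICC(3,1) test-retest consistency of parcel-edge contrast series.

The consistency form of the intraclass correlation coefficient for a
two-way mixed model with single measurements,

    ICC(3,1) = (BMS − EMS) / (BMS + (k − 1) EMS),

where BMS and EMS are the between-subjects and residual mean squares of
the subjects × sessions ANOVA decomposition and k is the number of
sessions (here k = 2).  This form measures the consistency of the
subject ranking across sessions and is insensitive to additive session
offsets.  Confidence intervals use the Shrout–Fleiss F-based construction:
with F = BMS/EMS and degrees of freedom (n−1, (n−1)(k−1)),

    FL = F / F_{1−α/2}(n−1, (n−1)(k−1)),
    FU = F · F_{1−α/2}((n−1)(k−1), n−1),

mapped through g(x) = (x − 1)/(x + k − 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ICC_THRESHOLD = 0.4
REPLICATION_ICC_THRESHOLD = 0.5


class IccUndefinedError(ValueError):
    """Both variance components are zero: the ICC is undefined."""


@dataclass
class ICCComponents:
    """Mean squares of the subjects × sessions ANOVA (no replicates)."""

    BMS: float  # between-subjects mean square
    JMS: float  # between-sessions mean square (reported, unused by ICC(3,1))
    EMS: float  # residual (error) mean square
    n: int  # subjects
    k: int  # sessions

    @property
    def df_between(self) -> int:
        return self.n - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    label: str  # 'consistent' | 'inconsistent'
    threshold: float
    components: ICCComponents | None = None


def icc_components(matrix: np.ndarray) -> ICCComponents:
    """Two-way ANOVA decomposition of an n_subjects × k matrix.

    BMS from subject means, JMS from session means, EMS from the residual
    after removing both main effects.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n_subjects x k matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in the subject x session matrix")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_subjects = k * np.sum((row_means - gm) ** 2)
    ss_sessions = n * np.sum((col_means - gm) ** 2)
    ss_total = np.sum((x - gm) ** 2)
    ss_resid = ss_total - ss_subjects - ss_sessions
    ss_resid = max(ss_resid, 0.0)  # guard tiny negative rounding
    return ICCComponents(
        BMS=ss_subjects / (n - 1),
        JMS=ss_sessions / (k - 1),
        EMS=ss_resid / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_3_1(components: ICCComponents) -> float:
    """ICC(3,1) = (BMS − EMS) / (BMS + (k − 1) EMS)."""
    bms, ems, k = components.BMS, components.EMS, components.k
    if bms == 0.0 and ems == 0.0:
        raise IccUndefinedError("zero variance in both components; ICC undefined")
    return (bms - ems) / (bms + (k - 1) * ems)


def icc_ci(components: ICCComponents, conf: float = 0.95) -> tuple[float, float]:
    """Shrout–Fleiss F-based confidence interval for ICC(3,1)."""
    bms, ems, k = components.BMS, components.EMS, components.k
    icc = icc_3_1(components)
    if ems == 0.0:
        warnings.warn("EMS is zero; confidence interval collapses to the point estimate")
        return (icc, icc)
    df1, df2 = components.df_between, components.df_error
    if df1 <= 0 or df2 <= 0:
        raise ValueError("insufficient degrees of freedom for a confidence interval")
    alpha = 1.0 - conf
    f0 = bms / ems
    fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)

    def g(x: float) -> float:
        return (x - 1.0) / (x + k - 1.0)

    return (g(fl), g(fu))


def classify(icc: float, threshold: float = DEFAULT_ICC_THRESHOLD) -> str:
    """'consistent' iff icc is strictly above the threshold."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite for classification")
    return "consistent" if icc > threshold else "inconsistent"


def icc_report(matrix: np.ndarray, threshold: float = DEFAULT_ICC_THRESHOLD, conf: float = 0.95) -> ICCResult:
    """Full per-edge result: components, ICC, CI, consistency label.

    A degenerate edge (zero variance in both components) is labeled
    inconsistent and logged rather than propagating an error.
    """
    comp = icc_components(matrix)
    try:
        icc = icc_3_1(comp)
    except IccUndefinedError:
        logger.warning("degenerate edge (BMS = EMS = 0); labeled inconsistent")
        return ICCResult(icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                         label="inconsistent", threshold=threshold, components=comp)
    low, high = icc_ci(comp, conf)
    return ICCResult(icc=icc, ci_low=low, ci_high=high,
                     label=classify(icc, threshold), threshold=threshold, components=comp)


def icc_3_1_many(matrices: np.ndarray) -> np.ndarray:
    """Vectorized ICC(3,1) over a stack of matrices, shape (m, n, k).

    Used for calibration studies over many simulated edges; degenerate
    edges yield NaN.
    """
    x = np.asarray(matrices, dtype=float)
    m, n, k = x.shape
    gm = x.mean(axis=(1, 2), keepdims=True)
    row_means = x.mean(axis=2, keepdims=True)
    col_means = x.mean(axis=1, keepdims=True)
    ss_subjects = k * ((row_means - gm) ** 2).sum(axis=(1, 2))
    ss_sessions = n * ((col_means - gm) ** 2).sum(axis=(1, 2))
    ss_total = ((x - gm) ** 2).sum(axis=(1, 2))
    bms = ss_subjects / (n - 1)
    ems = np.maximum(ss_total - ss_subjects - ss_sessions, 0.0) / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (bms - ems) / denom
    out[denom == 0] = np.nan
    return out
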