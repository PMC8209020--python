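"""Group summaries, two-sample t-tests, and stain marker ratios.

Per-image (or per-sample) morphometric parameters are summarized as
mean ± SEM and compared between two groups with a two-tailed two-sample
t-test.  Both the classical Student (pooled, df = n_a + n_b - 2) and the
Welch variant are available; tests can be run either from raw values or from
printed summary statistics (n, mean, SEM), which is exact whenever the
summaries are.  Missing values (e.g., undefined thickness on empty images)
are excluded with a logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedRatioError, ValidationError

__all__ = [
    "GroupStats",
    "TTestResult",
    "MarkerRatio",
    "group_summary",
    "ttest",
    "marker_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupStats:
    """Sample count, mean and standard error of one parameter in one group."""

    n: int
    mean: float
    sem: float
    parameter_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(
                f"GroupStats requires n >= 2, got n={self.n}"
            )
        if self.sem < 0:
            raise ValidationError(f"sem: must be >= 0, got {self.sem}")


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed two-sample t-test outcome."""

    t_statistic: float
    df: float
    p_value: float
    variant: str  # "student" (pooled df) or "welch"
    source: str  # "raw-values" or "summary-stats"


@dataclass(frozen=True)
class MarkerRatio:
    """Ratio of two stains' positive-area means, with first-order SE."""

    ratio: float
    se: float


def group_summary(
    values: Sequence[float], parameter_name: str = "", units: str = ""
) -> GroupStats:
    """Mean and SEM (sample s.d. over sqrt(n)) of per-image values.

    NaN entries — e.g., undefined thickness from empty images — are dropped
    with a logged count before computing the summary.
    """
    arr = np.asarray(list(values), dtype=float)
    finite = arr[np.isfinite(arr)]
    n_missing = arr.size - finite.size
    if n_missing:
        logger.info(
            "group_summary(%s): excluded %d missing value(s)",
            parameter_name or "<unnamed>",
            n_missing,
        )
    if finite.size < 2:
        raise InsufficientDataError(
            f"need >= 2 non-missing values, got {finite.size}"
        )
    n = int(finite.size)
    mean = float(finite.mean())
    sem = float(finite.std(ddof=1) / np.sqrt(n))
    return GroupStats(n=n, mean=mean, sem=sem, parameter_name=parameter_name, units=units)


def _as_stats(group, name: str) -> tuple[GroupStats, str]:
    if isinstance(group, GroupStats):
        return group, "summary-stats"
    return group_summary(group, parameter_name=name), "raw-values"


def ttest(a, b, variant: str = "student") -> TTestResult:
    """Two-tailed two-sample t-test between groups ``a`` and ``b``.

    Each group is either a :class:`GroupStats` or a sequence of raw values.
    The statistic is ``t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2)``;
    the Student variant uses pooled degrees of freedom ``n_a + n_b - 2``
    while the Welch variant uses the Welch–Satterthwaite approximation.
    With zero variance in both groups the conventions are p = 1 for equal
    means and p = 0 (with a warning) otherwise.
    """
    if variant not in ("student", "welch"):
        raise ValidationError(
            f"variant: expected 'student' or 'welch', got {variant!r}"
        )
    sa, source_a = _as_stats(a, "a")
    sb, source_b = _as_stats(b, "b")
    source = source_a if source_a == source_b else "mixed"
    se = float(np.hypot(sa.sem, sb.sem))
    diff = sa.mean - sb.mean
    if variant == "student":
        df = float(sa.n + sb.n - 2)
    else:
        va, vb = sa.sem**2, sb.sem**2
        denom = va**2 / (sa.n - 1) + vb**2 / (sb.n - 1)
        df = float((va + vb) ** 2 / denom) if denom > 0 else float(sa.n + sb.n - 2)
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, variant, source)
        warnings.warn(
            "zero variance with unequal means; reporting p = 0", stacklevel=2
        )
        t = float(np.inf) if diff > 0 else float(-np.inf)
        return TTestResult(t, df, 0.0, variant, source)
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, variant, source)


def marker_ratio(dense_marker: GroupStats, sparse_marker: GroupStats) -> MarkerRatio:
    """Ratio of a dense stain's positive-area mean to a sparse stain's.

    Used to express e.g. how much more of the tissue a pan-Schwann-cell
    stain covers than a sympathetic-fiber stain.  The standard error is the
    first-order propagation
    ``sqrt((sem_a/mean_b)^2 + (mean_a*sem_b/mean_b^2)^2)``.
    """
    if sparse_marker.mean <= 0:
        raise UndefinedRatioError(
            f"sparse marker mean must be > 0, got {sparse_marker.mean}"
        )
    ratio = dense_marker.mean / sparse_marker.mean
    se = float(
        np.hypot(
            dense_marker.sem / sparse_marker.mean,
            dense_marker.mean * sparse_marker.sem / sparse_marker.mean**2,
        )
    )
    return MarkerRatio(ratio=float(ratio), se=se)
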