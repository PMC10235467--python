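"""Normality-gated two-sample inference with Benjamini-Hochberg FDR control.

The workflow for each pairwise comparison: Anderson-Darling normality on both samples
(alpha = 0.05); if both pass, an F-test on the variances (alpha = 0.05) chooses
pooled vs Welch one-tailed t; if either fails, a one-tailed Mann-Whitney U (exact for
small samples, normal approximation with tie correction otherwise).  The full
decision trail is recorded on every result.  Raw p-values are then adjusted within a
comparison family by the Benjamini-Hochberg step-up with the q = 0.1 threshold, and
tiered as * (p < 0.1), ** (p < 0.05), *** (p < 0.01), exclusive boundaries.

Tail direction is always explicit per comparison (``tail="greater"`` tests the
alternative that the first sample's location exceeds the second's); it is never
inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

NORMALITY_ALPHA = 0.05
VARIANCE_ALPHA = 0.05
FDR_Q = 0.1
#: above this per-group size the Mann-Whitney p uses the tie-corrected normal
#: approximation; at or below it, exact enumeration
MANNWHITNEY_EXACT_N = 20


class InsufficientSampleError(ValueError):
    """Raised when a sample is too small for the adaptive test (n < 3)."""


@dataclass
class TestResult:
    """One pairwise comparison's full decision trail and outcome.

    ``p_adj``, ``rejected`` and ``tier`` are populated by :func:`adjust_family`;
    before adjustment they are NaN/False/"".
    """

    label: str
    n_x: int
    n_y: int
    ad_p_x: float
    ad_p_y: float
    variance_p: float  # NaN when the Mann-Whitney branch was taken
    test: str  # "t pooled" | "t Welch" | "mann-whitney" | "degenerate"
    tail: str
    p_raw: float
    p_adj: float = math.nan
    rejected: bool = False
    tier: str = ""
    extra: dict = field(default_factory=dict)


def adaptive_two_sample_test(
    x: np.ndarray,
    y: np.ndarray,
    tail: str = "greater",
    label: str = "",
) -> TestResult:
    """Normality-gated one-tailed two-sample test.

    ``tail="greater"`` tests H1: location(x) > location(y); ``"less"`` the reverse.
    Both samples passing Anderson-Darling at alpha = 0.05 routes to a t-test (pooled
    or Welch per a two-sided F-test on the variances); either failing routes to
    Mann-Whitney.  Samples with zero variance in both groups yield a degenerate-data
    marker (p = NaN) rather than a test.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientSampleError(
            f"adaptive test needs n >= 3 per group, got {x.size} and {y.size}"
        )
    if np.var(x) == 0 and np.var(y) == 0:
        return TestResult(
            label=label, n_x=x.size, n_y=y.size,
            ad_p_x=math.nan, ad_p_y=math.nan, variance_p=math.nan,
            test="degenerate", tail=tail, p_raw=math.nan,
        )
    ad_p_x = _ad_pvalue(x)
    ad_p_y = _ad_pvalue(y)
    normal = ad_p_x >= NORMALITY_ALPHA and ad_p_y >= NORMALITY_ALPHA
    if normal:
        f_p = _variance_f_test(x, y)
        equal_var = f_p >= VARIANCE_ALPHA
        res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=tail)
        return TestResult(
            label=label, n_x=x.size, n_y=y.size,
            ad_p_x=ad_p_x, ad_p_y=ad_p_y, variance_p=f_p,
            test="t pooled" if equal_var else "t Welch",
            tail=tail, p_raw=float(res.pvalue),
        )
    method = (
        "exact"
        if max(x.size, y.size) <= MANNWHITNEY_EXACT_N and not _has_ties(x, y)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative=tail, method=method)
    return TestResult(
        label=label, n_x=x.size, n_y=y.size,
        ad_p_x=ad_p_x, ad_p_y=ad_p_y, variance_p=math.nan,
        test="mann-whitney", tail=tail, p_raw=float(res.pvalue),
        extra={"method": method},
    )


def _ad_pvalue(sample: np.ndarray) -> float:
    """Anderson-Darling composite-normality p-value."""
    if np.var(sample) == 0:
        return 0.0  # a point mass is maximally non-normal
    return float(normal_ad(sample)[1])


def _variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    p = stats.f.sf(f, x.size - 1, y.size - 1)
    return float(min(1.0, 2.0 * min(p, 1.0 - p)))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return np.unique(combined).size < combined.size


def bh_fdr_adjust(p_values, q: float = FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags at ``q``.

    Returns ``(adjusted, rejected)``; an empty input yields empty arrays.  Adjusted
    p-values follow the usual min-cumulation so they are monotone in the ranks, and
    ``rejected[i]`` is ``adjusted[i] <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, rejected


def significance_tier(p_adj: float) -> str:
    """Tier an adjusted p-value: ``***`` < 0.01, ``**`` < 0.05, ``*`` < 0.1, else ns.

    Boundaries are exclusive: exactly 0.1 is ``ns``.
    """
    if math.isnan(p_adj):
        return "ns"
    if p_adj < 0.01:
        return "***"
    if p_adj < 0.05:
        return "**"
    if p_adj < 0.1:
        return "*"
    return "ns"


def adjust_family(results: list[TestResult], q: float = FDR_Q) -> list[TestResult]:
    """BH-adjust one comparison family in place and fill tiers.

    Degenerate results (NaN raw p) are left unadjusted and flagged ``ns``.
    """
    valid = [r for r in results if not math.isnan(r.p_raw)]
    if valid:
        adjusted, rejected = bh_fdr_adjust([r.p_raw for r in valid], q=q)
        for r, p_adj, rej in zip(valid, adjusted, rejected):
            r.p_adj = float(p_adj)
            r.rejected = bool(rej)
            r.tier = significance_tier(r.p_adj)
    for r in results:
        if math.isnan(r.p_raw):
            r.tier = "ns"
    return results


__all__ = [
    "FDR_Q",
    "InsufficientSampleError",
    "MANNWHITNEY_EXACT_N",
    "NORMALITY_ALPHA",
    "TestResult",
    "VARIANCE_ALPHA",
    "adaptive_two_sample_test",
    "adjust_family",
    "bh_fdr_adjust",
    "significance_tier",
]
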