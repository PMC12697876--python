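"""Two-group test selection and multiplicity control.

The selector mirrors a common wet-lab statistics policy: Shapiro-Wilk
normality and Levene variance checks decide between the pooled t test,
the separate-variance (Welch) t test, and the Wilcoxon rank-sum
(Mann-Whitney U) test. The choice is always recorded in the result so
downstream tables can report which test produced each p value.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


@dataclass
class GroupComparisonResult:
    """Outcome of an automatically selected two-group comparison."""

    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float]
    effect_direction: str  # 'a>b', 'b>a', or 'none'
    normality_p: tuple[float, float]
    variance_p: float


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p value; nan (treated as pass) when n < 3 or constant data.

    A constant sample is degenerate for Shapiro-Wilk; we route it to the
    nonparametric branch by returning 0.
    """
    if len(x) < 3:
        return float("nan")
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def auto_two_group_test(
    a: Sequence[float], b: Sequence[float], alpha_gate: float = 0.05
) -> GroupComparisonResult:
    """Compare two independent samples with data-driven test selection.

    Decision tree: both samples normal (Shapiro-Wilk p >= ``alpha_gate``)
    and homoscedastic (Levene p >= gate) -> pooled t; normal but
    heteroscedastic -> Welch t; otherwise -> Mann-Whitney U (two-sided).
    Samples too small for Shapiro-Wilk (n < 3) are treated as passing
    the normality gate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs n >= 2")

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = all(np.isnan(p) or p >= alpha_gate for p in (pa, pb))
    try:
        p_var = float(sps.levene(a, b).pvalue)
    except Exception:  # degenerate (e.g. both constant) - call variances equal
        p_var = 1.0
    if np.isnan(p_var):
        p_var = 1.0

    if normal and p_var >= alpha_gate:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "pooled-t"
    elif normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "welch-t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "rank-sum"

    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant samples
        p = 1.0
    diff = float(np.mean(a) - np.mean(b))
    if diff > 0:
        direction = "a>b"
    elif diff < 0:
        direction = "b>a"
    else:
        direction = "none"
    return GroupComparisonResult(
        test_name=name,
        statistic=stat,
        p_raw=p,
        p_adjusted=None,
        effect_direction=direction,
        normality_p=(pa, pb),
        variance_p=p_var,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
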