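"""Repeatability and group-comparison statistics for MRS parameters.

Test-retest repeatability uses Bland-Altman analysis — arithmetic
differences for PDFF (already a bounded percentage), log-ratio
differences for strictly positive parameters (T1, T2, R2*) — plus an
ensemble coefficient of variation for positive data computed on the log
scale:

``s^2 = sum(d_i^2) / (2n)``,  ``CoV = 100 * sqrt(exp(s^2) - 1)``

with ``d_i`` the within-subject log differences.  Group comparisons run
the standard gated sequence: Shapiro-Wilk normality and Levene variance
tests, one-way ANOVA only if every group is normal and variances are
homogeneous, Tukey's HSD only if the ANOVA rejects at p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RepeatabilityResult",
    "GroupComparison",
    "bland_altman",
    "cov_log",
    "group_compare",
]


@dataclass
class RepeatabilityResult:
    """Bland-Altman bias, limits of agreement and ensemble CoV."""

    bias: float
    loa_low: float
    loa_high: float
    p_bias: float
    cov_percent: float
    scale: str  # "arithmetic" | "log-ratio"
    n_pairs: int

    def __post_init__(self) -> None:
        if not self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12:
            raise ValueError("limits of agreement must bracket the bias")
        if self.cov_percent < 0:
            raise ValueError("CoV must be nonnegative")


def bland_altman(x1, x2, scale: str = "log-ratio") -> RepeatabilityResult:
    """Repeatability of paired measurements (repeat 1 vs repeat 2).

    ``scale="arithmetic"`` analyses plain differences (used for PDFF);
    ``scale="log-ratio"`` analyses ``log(x2/x1)`` and reports bias and
    limits on the log scale (multiplicative).  The bias test is a paired
    (one-sample-on-differences) t-test.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.size < 2:
        raise ValueError("need at least two matched pairs")
    if scale == "log-ratio":
        if np.any(x1 <= 0) or np.any(x2 <= 0):
            raise ValueError("log-ratio scale requires strictly positive values")
        d = np.log(x2 / x1)
        cov = cov_log(x1, x2)
    elif scale == "arithmetic":
        d = x2 - x1
        m = (x1 + x2) / 2.0
        mean_level = float(np.mean(m))
        cov = (
            100.0 * float(np.std(d, ddof=1)) / (math.sqrt(2.0) * mean_level)
            if mean_level > 0
            else float("nan")
        )
    else:
        raise ValueError("scale must be 'arithmetic' or 'log-ratio'")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t = stats.ttest_1samp(d, 0.0)
    return RepeatabilityResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        p_bias=float(t.pvalue),
        cov_percent=max(cov, 0.0) if np.isfinite(cov) else cov,
        scale=scale,
        n_pairs=int(x1.size),
    )


def cov_log(x1, x2) -> float:
    """Ensemble coefficient of variation (percent) for positive data.

    Within-subject variance on the log scale is ``s^2 = sum(d^2)/(2n)``
    over the paired log differences; the CoV is
    ``100*sqrt(exp(s^2)-1)``.  Invariant under rescaling all values by a
    common factor.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("ensemble CoV requires strictly positive values")
    d = np.log(x2) - np.log(x1)
    s2 = float(np.sum(d**2) / (2.0 * d.size))
    return 100.0 * math.sqrt(math.exp(s2) - 1.0)


@dataclass
class GroupComparison:
    """Gated normality/variance/ANOVA/Tukey sequence outcome."""

    groups: list[str]
    excluded: list[str]
    shapiro_p: dict[str, float]
    levene_p: float
    normal: bool
    homoscedastic: bool
    anova_p: float | None  # None when gated off
    significant: bool
    tukey: "object | None"  # scipy TukeyHSDResult when run
    alpha: float = 0.05


def group_compare(
    groups: dict[str, np.ndarray], alpha: float = 0.05, min_size: int = 3
) -> GroupComparison:
    """Compare a parameter across disease-state groups.

    Groups smaller than ``min_size`` are excluded with a warning.  ANOVA
    runs only when all groups pass Shapiro-Wilk normality and Levene's
    variance test at ``alpha``; Tukey's HSD runs only when the ANOVA
    rejects.
    """
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < min_size:
            excluded.append(name)
            warnings.warn(
                f"group '{name}' has fewer than {min_size} values; excluded",
                stacklevel=2,
            )
        else:
            usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")

    shapiro_p = {}
    for name, vals in usable.items():
        if np.ptp(vals) == 0:
            shapiro_p[name] = 1.0  # degenerate constant group: treat as normal
        else:
            shapiro_p[name] = float(stats.shapiro(vals).pvalue)
    normal = all(p > alpha for p in shapiro_p.values())
    levene_p = float(stats.levene(*usable.values()).pvalue)
    homoscedastic = levene_p > alpha

    anova_p: float | None = None
    tukey = None
    significant = False
    if normal and homoscedastic:
        anova_p = float(stats.f_oneway(*usable.values()).pvalue)
        if anova_p < alpha:
            significant = True
            tukey = stats.tukey_hsd(*usable.values())
    return GroupComparison(
        groups=list(usable),
        excluded=excluded,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        normal=normal,
        homoscedastic=homoscedastic,
        anova_p=anova_p,
        significant=significant,
        tukey=tukey,
        alpha=alpha,
    )
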