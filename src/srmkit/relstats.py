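"""Test-retest reliability and group-comparison statistics.

Implements the analysis layer the battery's validation rests on:
test-retest Pearson correlations, Fisher z comparison of two independent
correlations, Holm step-down multiple-comparison correction, Bland-Altman
bias and coefficient of reliability (COR = 1.96 x SD of the
between-session differences; limits of agreement = bias +/- COR),
3-standard-deviation outlier rejection against a reference distribution,
pooled-variance two-sample t tests computed directly from group summaries
(n, mean, SD) with Cohen's d, a default-prior JZS Bayes factor, and
scoring of the 25-item hearing handicap inventory (HHIA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSessions",
    "GroupSummary",
    "BlandAltmanResult",
    "pearson_r",
    "fisher_z_compare",
    "holm_adjust",
    "bland_altman",
    "outlier_reject_3sd",
    "summary_ttest",
    "jzs_bf10",
    "hhia_score",
    "HHIA_POINTS",
]


@dataclass(frozen=True)
class PairedSessions:
    """Per-subject thresholds from two sessions of one measure."""

    session1: np.ndarray
    session2: np.ndarray

    def __post_init__(self):
        s1 = np.asarray(self.session1, dtype=float)
        s2 = np.asarray(self.session2, dtype=float)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("sessions must be equal-length 1-d arrays")
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise ValueError("sessions must be finite")
        object.__setattr__(self, "session1", s1)
        object.__setattr__(self, "session2", s2)

    @property
    def n(self) -> int:
        return len(self.session1)

    @property
    def differences(self) -> np.ndarray:
        """Session 2 minus session 1."""
        return self.session2 - self.session1


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sd) for one measure in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, coefficient of reliability, and limits of agreement."""

    bias: float
    cor: float

    @property
    def limits(self) -> tuple[float, float]:
        return (self.bias - self.cor, self.bias + self.cor)


def pearson_r(pairs: PairedSessions) -> tuple[float, float]:
    """Product-moment test-retest correlation with two-sided p."""
    if pairs.n < 4:
        raise ValueError("need at least 4 pairs for a correlation")
    if np.std(pairs.session1) == 0 or np.std(pairs.session2) == 0:
        raise ValueError("degenerate (constant) session values")
    res = stats.pearsonr(pairs.session1, pairs.session2)
    return float(res.statistic), float(res.pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bland_altman(pairs: PairedSessions) -> BlandAltmanResult:
    """Bias (mean session-2-minus-session-1 difference) and COR
    (1.96 x sample SD of the differences)."""
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return BlandAltmanResult(bias=bias, cor=1.96 * sd)


def outlier_reject_3sd(
    values, reference_mean: float, reference_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, rejected) by the |v - mean| <= 3 sd rule."""
    if reference_sd <= 0:
        raise ValueError("reference sd must be positive")
    v = np.asarray(values, dtype=float)
    keep = np.abs(v - reference_mean) <= 3.0 * reference_sd
    return v[keep], v[~keep]


def summary_ttest(g1: GroupSummary, g2: GroupSummary):
    """Pooled-variance two-sample t test from group summaries.

    Returns (t, df, p, mean difference, Cohen's d) with
    df = n1 + n2 - 2 and d = |mean difference| / pooled sd.
    """
    df = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    if pooled_var == 0:
        if g1.mean == g2.mean:
            return 0.0, df, 1.0, 0.0, 0.0
        raise ValueError("zero pooled variance with unequal means")
    diff = g1.mean - g2.mean
    se = np.sqrt(pooled_var * (1.0 / g1.n + 1.0 / g2.n))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = abs(diff) / np.sqrt(pooled_var)
    return float(t), int(df), float(p), float(diff), float(d)


def jzs_bf10(t: float, n1: int, n2: int, scale: float = 0.707) -> float:
    """Two-sample JZS (Cauchy-prior) Bayes factor BF10 by numerical
    integration; an approximation suited to order-of-magnitude use.

    Uses the effective sample size N = n1*n2/(n1+n2), df = n1+n2-2, and
    a Cauchy prior with the given scale on standardized effect size.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    n_eff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    r2 = scale**2

    def integrand(g: float) -> float:
        return (
            (1.0 + n_eff * g) ** -0.5
            * (1.0 + t**2 / ((1.0 + n_eff * g) * nu)) ** (-(nu + 1) / 2.0)
            * (r2 / (2.0 * np.pi)) ** 0.5
            * g ** -1.5
            * np.exp(-r2 / (2.0 * g))
        )

    numerator, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(numerator) or numerator <= 0:
        raise RuntimeError(f"Bayes-factor integration failed (value {numerator}, err {err})")
    denominator = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(numerator / denominator)


HHIA_POINTS = {"no": 0, "a veces": 2, "sí": 4, "si": 4}


def hhia_score(responses) -> int:
    """Total hearing-handicap score: 25 items, each no=0 / a veces=2 /
    sí=4, summed without sub-scales; range 0-100."""
    items = list(responses)
    if len(items) != 25:
        raise ValueError(f"need exactly 25 answers, got {len(items)}")
    total = 0
    for ans in items:
        if isinstance(ans, str):
            key = ans.strip().lower()
            if key not in HHIA_POINTS:
                raise ValueError(f"unrecognized answer {ans!r}")
            total += HHIA_POINTS[key]
        elif ans in (0, 2, 4):
            total += int(ans)
        else:
            raise ValueError(f"answers must be no/a veces/sí or 0/2/4, got {ans!r}")
    return total
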