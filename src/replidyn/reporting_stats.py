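"""Shared statistical tests and interval estimates.

Every hypothesis test in the pipeline goes through this module so that the
reported statistic, sample sizes, effect and 95% CI are uniform across stages.
Conventions:

* "t test" between two independent groups is always Welch's unequal-variance
  t (group sizes and variances differ throughout these experiments).
* The two-group nonparametric test is the Wilcoxon rank-sum (Mann-Whitney U)
  with midrank ties; exact null distribution for small samples, normal
  approximation with continuity correction otherwise.
* No multiple-testing correction is applied; reports carry raw p-values.

Degenerate inputs (zero variance, complete ties) are resolved by explicit
conventions and flagged on the result rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "welch_t",
    "wilcoxon_ranksum",
    "paired_t",
    "ci95_mean",
    "significance_stars",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``effect`` is a difference (t tests) or location contrast, with its 95% CI
    where available; ``flags`` collects degenerate-input conventions applied.
    """

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect: float
    ci95: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "effect": self.effect,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "stars": self.stars,
            "flags": self.flags,
        }


def significance_stars(p: float) -> str:
    """Star convention matching the figure legends (*** for p < 0.001)."""
    if math.isnan(p):
        return "n/a"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    return a


def welch_t(a, b) -> TestResult:
    """Two-sample unequal-variance t test (Welch-Satterthwaite df), two-sided.

    Effect is ``mean(a) - mean(b)`` with a 95% CI from the Welch standard
    error.  If both groups have zero variance and equal means, p = 1 by
    convention (flagged).
    """
    a, b = _as_1d(a), _as_1d(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    effect = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    flags: list[str] = []
    if va == 0.0 and vb == 0.0:
        if effect == 0.0:
            return TestResult("welch_t", 0.0, 1.0, (a.size, b.size), 0.0,
                              (0.0, 0.0), ["zero variance in both groups, equal means"])
        flags.append("zero variance in both groups, unequal means")
        return TestResult("welch_t", math.inf if effect > 0 else -math.inf, 0.0,
                          (a.size, b.size), effect, (effect, effect), flags)
    res = stats.ttest_ind(a, b, equal_var=False)
    se = math.sqrt(va / a.size + vb / b.size)
    df = res.df
    half = stats.t.ppf(0.975, df) * se
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), effect, (effect - half, effect + half), flags)


def wilcoxon_ranksum(a, b) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test, two-sided.

    Exact enumeration when both samples have <= 10 observations and no ties
    across groups; otherwise the normal approximation with midrank ties and
    continuity correction.  Effect is the Hodges-Lehmann shift
    ``median(a_i - b_j)``.  All values tied across both groups gives p = 1
    (flagged).
    """
    a, b = _as_1d(a), _as_1d(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("wilcoxon_ranksum requires at least 2 observations per group")
    hl = float(np.median(np.subtract.outer(a, b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult("wilcoxon_ranksum", float(a.size * b.size / 2), 1.0,
                          (a.size, b.size), 0.0, None, ["all values tied across groups"])
    has_cross_ties = bool(np.intersect1d(a, b).size)
    if a.size <= 10 and b.size <= 10 and not has_cross_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult("wilcoxon_ranksum", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), hl)


def paired_t(diffs) -> TestResult:
    """One-sample t test on paired differences, two-sided.

    Conventions on degenerate input: all-zero differences -> p = 1 (flagged,
    "no paired effect measurable"); constant nonzero differences -> p = 0
    (flagged), since the effect is reproduced exactly in every pair.
    """
    d = _as_1d(diffs)
    if d.size < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    effect = float(d.mean())
    if d.var(ddof=1) == 0.0:
        if effect == 0.0:
            return TestResult("paired_t", 0.0, 1.0, (d.size,), 0.0, (0.0, 0.0),
                              ["all paired differences zero"])
        return TestResult("paired_t", math.inf if effect > 0 else -math.inf, 0.0,
                          (d.size,), effect, (effect, effect),
                          ["zero-variance nonzero differences"])
    res = stats.ttest_1samp(d, 0.0)
    lo, hi = ci95_mean(d)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                      (d.size,), effect, (lo, hi))


def ci95_mean(values) -> tuple[float, float]:
    """95% CI for the mean: ``mean +/- t(0.975, n-1) * SE``."""
    v = _as_1d(values)
    if v.size < 2:
        raise ValueError("ci95_mean requires at least 2 observations")
    se = v.std(ddof=1) / math.sqrt(v.size)
    half = stats.t.ppf(0.975, v.size - 1) * se
    m = float(v.mean())
    return (m - half, m + half)
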