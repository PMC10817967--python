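"""Group-level comparisons of band powers across scan protocols.

Two designs are covered: paired comparison of one- vs two-slice band powers
per subject (two-tailed paired t, Bonferroni-corrected across the three
physiological bands), and comparison across slice thicknesses (one-way
ANOVA with Tukey HSD post-hocs, plus the rank-based Kruskal-Wallis
alternative). Shapiro-Wilk checks normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "StatResult",
    "paired_t_bonferroni",
    "oneway_anova_tukey",
    "kruskal_wallis",
    "normality_check",
]


@dataclass
class StatResult:
    """One hypothesis-test outcome."""

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    p_adjusted: float | None = None
    correction: str | None = None
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "correction": self.correction,
            "groups": list(self.groups),
        }


def paired_t_bonferroni(
    a, b, m: int = 3, labels: tuple[str, str] = ("a", "b")
) -> StatResult:
    """Two-tailed paired t-test with Bonferroni correction over m comparisons.

    df = n − 1; p_adjusted = min(1, m·p). The default m = 3 corrects across
    the three physiological bands tested together.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if m < 1:
        raise ValueError("m must be >= 1")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0) and not np.allclose(diffs, 0):
        raise ValueError("zero-variance non-zero differences")
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = scipy.stats.ttest_rel(a, b)
    return StatResult(
        test="paired t (two-tailed)",
        statistic=float(t_stat),
        df=n - 1,
        p=float(p),
        p_adjusted=min(1.0, m * float(p)),
        correction=f"Bonferroni (m={m})",
        groups=labels,
    )


def oneway_anova_tukey(
    groups: list, labels: list[str] | None = None
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA across >= 3 groups plus Tukey HSD pairwise post-hocs.

    Returns the omnibus F test (df = (k−1, N−k)) and one StatResult per
    group pair with the family-wise adjusted Tukey p. Unequal group sizes
    use the Tukey-Kramer variant (scipy's tukey_hsd).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n_total = sum(g.size for g in groups)
    df_between, df_within = k - 1, n_total - k
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in range(1)):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = scipy.stats.f_oneway(*groups)
        if not np.isfinite(f_stat):  # identical groups -> 0/0
            f_stat, p = 0.0, 1.0
    omnibus = StatResult(
        test="one-way ANOVA",
        statistic=float(f_stat),
        df=(df_between, df_within),
        p=float(p),
        groups=tuple(labels),
    )
    pairwise: list[StatResult] = []
    tukey = scipy.stats.tukey_hsd(*groups)
    for i in range(k):
        for j in range(i + 1, k):
            pairwise.append(
                StatResult(
                    test="Tukey HSD",
                    statistic=float(tukey.statistic[i, j]),
                    df=df_within,
                    p=float(tukey.pvalue[i, j]),
                    p_adjusted=float(tukey.pvalue[i, j]),
                    correction="Tukey HSD (family-wise)",
                    groups=(labels[i], labels[j]),
                )
            )
    return omnibus, pairwise


def kruskal_wallis(groups: list, labels: list[str] | None = None) -> StatResult:
    """Kruskal-Wallis rank test across >= 3 groups.

    The rank-based alternative to the parametric ANOVA for the same
    slice-thickness design; H = 0 with p = 1 for identical groups.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = scipy.stats.kruskal(*groups)
    return StatResult(
        test="Kruskal-Wallis",
        statistic=float(h_stat),
        df=len(groups) - 1,
        p=float(p),
        groups=tuple(labels),
    )


def normality_check(values) -> StatResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w_stat, p = scipy.stats.shapiro(values)
    return StatResult(
        test="Shapiro-Wilk", statistic=float(w_stat), df=None, p=float(p)
    )
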