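"""Statistical comparisons: Wilcoxon signed-rank (exact and normal modes),
two-sample Kolmogorov-Smirnov, and Student's t-tests with Bonferroni
correction.

The Wilcoxon exact mode enumerates all sign assignments (feasible up to
n = 15 pairs) and therefore gives exact small-sample p values even with
midranked ties; the normal mode reports the tie-corrected z approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "ks_two_sample",
    "t_test_bonferroni",
    "two_sided_p_from_z",
]

_EXACT_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    n: int
    z: float | None = None
    sided: str = "two-sided"
    correction: str | None = None
    corrected_alpha: float | None = None
    significant: bool | None = None
    comparison: tuple[str, str] | None = None

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p value outside [0, 1]")


def two_sided_p_from_z(z: float) -> float:
    """Two-sided normal-approximation p for a given z value."""
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float],
                         mode: str = "auto") -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped and ties receive midranks.  The statistic W
    is the smaller of the positive and negative rank sums.  ``exact`` mode
    enumerates all 2^n sign patterns (n <= 15); ``normal`` mode uses the
    tie-corrected Gaussian approximation, reporting z with the sign of the
    positive-rank excess.  ``auto`` picks exact for n <= 15.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if mode == "auto":
        mode = "exact" if n <= _EXACT_MAX_N else "normal"
    if mode == "normal" and n < 5:
        raise ValueError("normal mode needs at least 5 non-zero differences")

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    if mode == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact mode limited to n <= {_EXACT_MAX_N}")
        # distribution of the positive rank sum over all sign assignments
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        sums = signs @ ranks
        p = min(1.0, 2.0 * float(np.mean(sums <= w + 1e-9)))
        return TestResult("wilcoxon_signed_rank_exact", w, p, int(n))

    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise ValueError("zero variance in normal approximation")
    z = (w_pos - mu) / np.sqrt(var)
    return TestResult("wilcoxon_signed_rank_normal", w, two_sided_p_from_z(z),
                      int(n), z=float(z))


def ks_two_sample(sample1: Sequence[float], sample2: Sequence[float]) -> TestResult:
    """Two-sample KS test: D = sup |ECDF1 - ECDF2| with asymptotic p."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(s1, s2, method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue),
                      int(s1.size + s2.size))


def t_test_bonferroni(groups: dict[str, Sequence[float]],
                      comparisons: Sequence[tuple[str, str]],
                      alpha: float = 0.05) -> list[TestResult]:
    """Two-sided Student's t-test per listed pair with Bonferroni threshold.

    Raw p values are reported alongside the adjusted significance decision at
    ``alpha / len(comparisons)``.
    """
    if not comparisons:
        raise ValueError("no comparisons listed")
    thr = alpha / len(comparisons)
    out = []
    for g1, g2 in comparisons:
        x = np.asarray(groups[g1], dtype=float)
        y = np.asarray(groups[g2], dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("each sample needs at least 2 observations")
        sp = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        if sp == 0 and x.mean() == y.mean():
            raise ValueError(f"zero pooled variance for {g1} vs {g2}")
        res = sps.ttest_ind(x, y, equal_var=True)
        p = float(res.pvalue)
        out.append(TestResult("t_test", float(res.statistic), p,
                              int(x.size + y.size),
                              correction="bonferroni", corrected_alpha=thr,
                              significant=bool(p < thr), comparison=(g1, g2)))
    return out
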