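"""Paired tests used in the concordance evaluation.

The Wilcoxon signed-rank test is implemented here with an exact null
distribution for small samples: zero differences are dropped (Wilcoxon's
convention), absolute differences receive midranks, and the distribution of
the positive-rank sum W+ over all 2^n equiprobable sign assignments is built
by a subset-sum convolution over doubled midranks (doubling keeps tied
midranks integral).  For more than 25 nonzero pairs a normal approximation
with continuity and tie correction is used.  The two-sided p-value is the
doubled smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "wilcoxon_signed_rank", "chi_square_2x2", "EXACT_LIMIT"]

#: largest number of nonzero pairs for which the exact distribution is used.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int  # pairs entering the test (nonzero differences for signed-rank)


def _exact_p(doubled_ranks: np.ndarray, w2: int) -> float:
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    counts /= counts.sum()
    lower = counts[: w2 + 1].sum()  # P(W+ <= w), on the doubled scale
    upper = counts[w2:].sum()  # P(W+ >= w)
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    With all differences zero the pair sets are identical and p = 1 by
    convention.  Raises ``ValueError`` for fewer than two nonzero pairs, where
    the test carries no information.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0)
    if n < 2:
        raise ValueError("signed-rank test needs at least 2 nonzero pairs")

    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _exact_p(doubled, w2)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return TestResult("wilcoxon_signed_rank", w_plus, 1.0, n)
        # continuity correction: shrink the deviation by 1/2 toward the mean
        dev = w_plus - mu
        dev = np.sign(dev) * max(0.0, abs(dev) - 0.5)
        z = dev / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult("wilcoxon_signed_rank", w_plus, p, n)


def chi_square_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Degenerate tables (a zero row or column margin) carry no information and
    return statistic 0, p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult("chi_square", 0.0, 1.0, int(arr.sum()))
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult("chi_square", float(res[0]), float(res[1]), int(arr.sum()))
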