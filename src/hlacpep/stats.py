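"""Statistical primitives: exact count tests and t-test wrappers.

The Fisher test here is the exact two-sided test on a 2x2 contingency
table, computed by summing hypergeometric probabilities of all tables
(with the observed margins) whose probability does not exceed that of
the observed table — the probability-mass convention.  Probabilities
are accumulated in exact rational arithmetic, so ties are handled
without a floating-point fudge factor.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps


def _check_counts(k1: int, n1: int, k2: int, n2: int) -> None:
    for k, n, label in ((k1, n1, "group 1"), (k2, n2, "group 2")):
        if n < 0 or k < 0 or k > n:
            raise ValueError(f"inconsistent counts in {label}: {k}/{n}")
    if n1 + n2 == 0:
        raise ValueError("both groups are empty")


def fisher_count_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact test for k1/n1 vs k2/n2 successes.

    Conditional on the margins, the count in group 1 follows a
    hypergeometric distribution; the two-sided p-value sums the
    probabilities of every table at most as probable as the observed
    one.  Exact rational arithmetic; symmetric under swapping groups.
    """
    _check_counts(k1, n1, k2, n2)
    n = n1 + n2
    m = k1 + k2  # successes overall
    denom = comb(n, m)
    lo = max(0, m - n2)
    hi = min(n1, m)
    probs = {a: Fraction(comb(n1, a) * comb(n2, m - a), denom) for a in range(lo, hi + 1)}
    p_obs = probs[k1]
    p = sum(q for q in probs.values() if q <= p_obs)
    return float(min(p, Fraction(1)))


def student_t_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided equal-variance (Student) t-test p-value."""
    return _t_pvalue(x, y, equal_var=True)


def welch_t_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value."""
    return _t_pvalue(x, y, equal_var=False)


def _t_pvalue(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test requires at least 2 observations per group")
    if np.std(x) == 0 and np.std(y) == 0:
        if np.mean(x) == np.mean(y):
            return 1.0
        raise ValueError("t-test undefined: both groups have zero variance and unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on zero variance (r undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same shape")
    # ptp, not std: accumulated rounding makes std of a constant vector tiny but nonzero
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined: zero variance in an input vector")
    return float(sps.pearsonr(x, y).statistic)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (reported for transparency, not used for flags)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(ranked)
    q[order] = np.minimum(ranked, 1.0)
    return q
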