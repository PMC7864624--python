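"""Classical tests used by the experiments, implemented from first
principles so each is checkable against an independent reference.

Only distribution functions (Student-t tail, the large-sample KS
distribution) come from scipy; the statistics, degrees of freedom and the exact small-sample
Kolmogorov-Smirnov p-value (lattice-path counting in exact integer
arithmetic) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb

import numpy as np
from scipy.stats import kstwo
from scipy.stats import t as t_dist

#: Study-wide significance level on corrected p-values.
ALPHA = 0.05

#: Sample-size bound up to which the two-sample KS p is computed exactly.
KS_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom (NaN where not
    applicable), raw and Bonferroni-corrected p, and the family size the
    correction used."""

    statistic: float
    df: float
    p_raw: float
    p_corrected: float
    family_size: int = 1

    def corrected(self, family_size: int) -> "TestResult":
        """Return a copy with the Bonferroni correction applied for the
        given family size."""
        return replace(
            self,
            p_corrected=bonferroni(self.p_raw, family_size),
            family_size=family_size,
        )

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p), the Bonferroni-corrected p-value."""
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p_raw!r}")
    return min(1.0, m * p_raw)


def one_sample_t(values, mu0: float) -> TestResult:
    """Two-sided one-sample t test of the sample mean against ``mu0``.

    A zero-variance sample is degenerate: p is 0 when the mean differs
    from ``mu0`` and 1 otherwise, with an infinite/zero statistic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    n = x.size
    mean = x.mean()
    s = x.std(ddof=1)
    df = float(n - 1)
    if s == 0.0:
        if mean == mu0:
            return TestResult(0.0, df, 1.0, 1.0)
        stat = np.inf if mean > mu0 else -np.inf
        return TestResult(float(stat), df, 0.0, 0.0)
    stat = (mean - mu0) / (s / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(stat), df))
    return TestResult(float(stat), df, min(p, 1.0), min(p, 1.0))


def two_sample_t_pooled(a, b) -> TestResult:
    """Two-sided pooled-variance two-sample t test, df = n_a + n_b - 2."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    na, nb = x.size, y.size
    df = float(na + nb - 2)
    pooled_var = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, 1.0)
        stat = np.inf if diff > 0 else -np.inf
        return TestResult(float(stat), df, 0.0, 0.0)
    stat = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(t_dist.sf(abs(stat), df))
    return TestResult(float(stat), df, min(p, 1.0), min(p, 1.0))


def welch_t(a, b) -> TestResult:
    """Two-sided Welch (unequal-variance) two-sample t test."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    va, vb = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    diff = x.mean() - y.mean()
    if va + vb == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float("nan"), 1.0, 1.0)
        stat = np.inf if diff > 0 else -np.inf
        return TestResult(float(stat), float("nan"), 0.0, 0.0)
    stat = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (x.size - 1) + vb**2 / (y.size - 1))
    p = 2.0 * float(t_dist.sf(abs(stat), df))
    return TestResult(float(stat), float(df), min(p, 1.0), min(p, 1.0))


def _ks_statistic_int(x: np.ndarray, y: np.ndarray) -> int:
    """max over the pooled support of |i*m - j*n| where i, j count sample
    values <= the support point.  D = result / (n*m).  Integer arithmetic
    keeps ties (heavily present in team metrics, which live on a 1/427
    grid) and boundary comparisons exact."""
    n, m = x.size, y.size
    support = np.unique(np.concatenate([x, y]))
    i = np.searchsorted(np.sort(x), support, side="right")
    j = np.searchsorted(np.sort(y), support, side="right")
    return int(np.max(np.abs(i * m - j * n)))


def _ks_exact_sf(c: int, n: int, m: int) -> float:
    """P(max |i*m - j*n| >= c) over uniformly random interleavings of n
    and m observations: exact lattice-path count.

    Counts the complement — monotone paths from (0,0) to (n,m) staying
    strictly inside the band |i*m - j*n| < c — with exact integers, then
    divides by C(n+m, n).  Assumes continuity (no cross-sample ties); with
    ties the result is conservative.
    """
    if c <= 0:
        return 1.0
    # A[j] = number of admissible paths reaching (i, j), rolled over i
    A = [0] * (m + 1)
    A[0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if abs(i * m - j * n) >= c:
                A[j] = 0
            elif j > 0:
                A[j] += A[j - 1]
        # A already accumulates the (i-1, j) contribution in place
    inside = A[m]
    return 1.0 - inside / comb(n + m, n)


def ks_two_sample(a, b) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    The p-value is exact (path counting) when both samples have at most
    ``KS_EXACT_MAX_N`` observations, and uses the Kolmogorov asymptote
    otherwise.  df is not applicable.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("need at least one observation per sample")
    n, m = x.size, y.size
    c = _ks_statistic_int(x, y)
    d = c / (n * m)
    if max(n, m) <= KS_EXACT_MAX_N:
        p = _ks_exact_sf(c, n, m)
    else:
        # finite-size-corrected asymptote: one-sample KS distribution at the
        # effective sample size n*m/(n+m); approaches the Kolmogorov limit
        # kolmogorov(sqrt(en)*d) from above as en grows
        en = n * m / (n + m)
        p = float(kstwo.sf(d, int(round(en))))
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(float(d), float("nan"), p, p)
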