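"""Small-sample exact tests implemented from first principles.

The study's association claims rest on three tests applied to tiny tables:
Fisher's exact test on 2x2 contingency tables (minimum-likelihood two-sided
definition), the Pearson chi-square test on r x c tables, and an exact
permutation Mann-Whitney U test.  Each is written directly from its
definition so that the published p-values can be reproduced at printed
precision; scipy is used only for the chi-square tail probability and for
the normal tail in the large-sample Mann-Whitney branch.
"""

from __future__ import annotations

import functools as _functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats


class StatTestError(ValueError):
    """Degenerate input for which the requested test is undefined."""


@dataclass
class ContingencyTable2x2:
    """Integer 2x2 cell counts; rows are levels of one factor, columns of the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or any(x != int(x) for x in cells):
            raise StatTestError(f"cells must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise StatTestError("all-zero table: test undefined")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sided: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise StatTestError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(k: int, r1: int, c1: int, n: int) -> float:
    # P(X = k) for X ~ Hypergeom(n, r1, c1): choose(r1,k)choose(n-r1,c1-k)/choose(n,c1)
    return (math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - k + 1)
            - math.lgamma(n - r1 - c1 + k + 1)
            - math.lgamma(n + 1) + math.lgamma(c1 + 1)
            + math.lgamma(n - c1 + 1))


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by the minimum-likelihood definition.

    Conditioning on both margins, cell ``a`` follows a hypergeometric
    distribution.  The two-sided p-value sums the point probabilities of
    every table in the support whose probability does not exceed that of the
    observed table (with a small relative tolerance against floating-point
    ties).  The sample odds ratio ``ad/bc`` is reported alongside; zero
    cells give 0 or infinity, flagged in ``extra``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:
        # margins admit a single table: no evidence either way
        p = 1.0
    else:
        logs = np.array([_log_hypergeom_pmf(k, r1, c1, n)
                         for k in range(lo, hi + 1)])
        probs = np.exp(logs - logs.max())
        probs /= probs.sum()
        p_obs = probs[a - lo]
        p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
        degenerate_or = True
    else:
        odds_ratio = (a * d) / (b * c)
        degenerate_or = False
    return TestResult(statistic=odds_ratio, p_value=min(p, 1.0),
                      method="fisher_exact",
                      extra={"odds_ratio": odds_ratio,
                             "degenerate_odds_ratio": degenerate_or})


# ---------------------------------------------------------------------------
# Pearson chi-square on r x c
# ---------------------------------------------------------------------------

def chi_square_rxc(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction.  Expected counts come from the product of the
    margins; a zero row or column margin makes the test undefined.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatTestError(f"table must be at least 2x2, got shape {obs.shape}")
    if (obs < 0).any():
        raise StatTestError("negative cell counts")
    n = obs.sum()
    if n <= 0:
        raise StatTestError("empty table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise StatTestError("zero row or column margin: chi-square undefined")
    expected = np.outer(row, col) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_scipy_stats.chi2.sf(chi2, df))
    return TestResult(statistic=chi2, p_value=p, method="chi_square",
                      extra={"df": df})


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks: np.ndarray, idx1, n1: int) -> float:
    r1 = float(ranks[list(idx1)].sum())
    return r1 - n1 * (n1 + 1) / 2.0


@_functools.lru_cache(maxsize=64)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for tie-free data: counts of subsets of size
    n1 from ranks 1..n1+n2 by U value (classic rank-sum recurrence)."""
    # f[k, u] = number of k-subsets of the first m items with U = u
    u_max = n1 * n2
    f = np.zeros((n1 + 1, u_max + 1), dtype=float)
    f[0, 0] = 1.0
    for m in range(1, n1 + n2 + 1):
        # adding item with rank m as a group-1 member raises U by (m - k)
        g = f.copy()
        for k in range(min(m, n1), 0, -1):
            shift = m - k
            if shift <= u_max:
                g[k, shift:] += f[k - 1, :u_max + 1 - shift]
        f = g
    return f[n1]


def mann_whitney_exact(group1: Sequence[float], group2: Sequence[float],
                       max_exact_n: int = 20,
                       max_exact_n_tie_free: int = 60) -> TestResult:
    """Two-sided Mann-Whitney U test, exact for small samples.

    U is computed from midranks (ties share their average rank), and the
    two-sided p-value is the null probability that U deviates from its mean
    n1*n2/2 at least as much as observed.  Tie-free data of combined size up
    to ``max_exact_n_tie_free`` use the exact null distribution of U from
    the rank-sum counting recurrence; tied data of combined size up to
    ``max_exact_n`` enumerate all C(n1+n2, n1) assignments of the observed
    values to the groups (ties handled naturally, since tied values give
    equal U under exchange).  Anything larger falls back to the normal
    approximation with tie-corrected variance.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise StatTestError("both groups must be non-empty")
    n1, n2 = x1.size, x2.size
    pooled = np.concatenate([x1, x2])
    ranks = _scipy_stats.rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    u_obs = _u_statistic(ranks, range(n1), n1)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)

    if not has_ties and n1 + n2 <= max_exact_n_tie_free:
        counts = _u_null_counts(n1, n2)
        u_vals = np.arange(counts.size)
        mask = np.abs(u_vals - mu) >= dev_obs - 1e-12
        p = float(counts[mask].sum() / counts.sum())
        method = "mann_whitney_exact"
    elif n1 + n2 <= max_exact_n:
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / total
        method = "mann_whitney_exact"
    else:
        # tie-corrected normal approximation
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all observations identical
        else:
            z = max(dev_obs - 0.5, 0.0) / math.sqrt(var)  # continuity-corrected
            p = 2.0 * float(_scipy_stats.norm.sf(z))
        method = "mann_whitney_normal"
    return TestResult(statistic=u_obs, p_value=min(p, 1.0), method=method)


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def summarize_median_range(values: Sequence[float]) -> dict:
    """Median and (min, max) of a non-empty sample; even n averages the central pair."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise StatTestError("empty sample")
    return {"median": float(np.median(x)),
            "min": float(x.min()),
            "max": float(x.max())}
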