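"""Nonparametric rank statistics and categorical association tests.

These are the procedures used throughout the analysis: Mann-Whitney U with
a rank-biserial effect size, Kruskal-Wallis, Spearman correlation, Pearson
chi-square and the two-tailed Fisher exact test.  They are implemented here
rather than delegated wholesale so that the reporting conventions are pinned:

* the reported U statistic is min(U, n1*n2 - U);
* the Mann-Whitney effect size is the rank-biserial correlation
  r = 1 - 2U/(n1*n2), negative when the first group is stochastically
  smaller;
* the Mann-Whitney p-value is computed by exact enumeration of the
  permutation distribution for small samples (combined n <= 16 by default)
  and by a tie-corrected normal approximation without continuity correction
  otherwise, which makes the two-group Kruskal-Wallis H equal z**2 exactly.

scipy supplies the underlying distributions (normal, chi-square, t,
hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero rank variance)."""


@dataclass
class TestResult:
    """Outcome of one hypothesis test, serializable to JSON."""

    test: str
    statistic: float
    p_value: float
    df: int | None = None
    effect_size: float | None = None
    n: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "df": self.df,
            "effect_size": None if self.effect_size is None else float(self.effect_size),
            "n": list(self.n),
        }


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1*n2) for a Mann-Whitney U."""
    return 1.0 - 2.0 * u / (n1 * n2)


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(x, y, exact_max_n: int = 16) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs (i, j) with x_i < y_j, ties counted half; the reported
    statistic is min(U, n1*n2 - U).  For combined sample size at most
    ``exact_max_n`` the p-value comes from full enumeration of group
    assignments (tie-aware); larger samples use the tie-corrected normal
    approximation.  The effect size is the rank-biserial correlation,
    negative when x is stochastically smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0  # pairs x > y, ties half
    u = n1 * n2 - u_greater  # pairs x < y, ties half
    m = n1 * n2
    effect = rank_biserial(u, n1, n2)

    if n1 + n2 <= exact_max_n:
        p = _mww_exact_p(ranks, n1, u)
    else:
        tie = _tie_term(pooled)
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u - m / 2.0) / np.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(
        test="mann_whitney",
        statistic=float(min(u, m - u)),
        p_value=p,
        effect_size=float(effect),
        n=(n1, n2),
    )


def _mww_exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-tailed exact p: fraction of assignments at least as far from
    n1*n2/2 as the observed U.  The permutation distribution is symmetric
    about n1*n2/2 even under ties."""
    n = ranks.size
    n2 = n - n1
    m = n1 * n2
    offset = n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - m / 2.0)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u_g = ranks[list(idx)].sum() - offset
        u = m - u_g
        if abs(u - m / 2.0) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; df = k - 1.

    A degenerate input with all values identical yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size].sum()
        h += r * r / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    df = len(groups) - 1
    if correction <= 0:  # every value identical
        return TestResult("kruskal_wallis", 0.0, 1.0, df=df, n=tuple(g.size for g in groups))
    h /= correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, df))
    return TestResult("kruskal_wallis", float(h), p, df=df, n=tuple(g.size for g in groups))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    Raises :class:`UndefinedStatisticError` when either variable has zero
    rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires equal-length samples of size >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("spearman undefined: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    n = x.size
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return TestResult("spearman", rho, p, df=n - 2, effect_size=rho, n=(n,))


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("pearson_chi2 requires a table with >= 2 rows and columns")
    if np.any(obs < 0) or np.any(obs % 1 != 0):
        raise ValueError("pearson_chi2 requires non-negative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0):
        raise ValueError(f"zero margin in row {int(np.argwhere(row == 0)[0][0])}")
    if np.any(col == 0):
        raise ValueError(f"zero margin in column {int(np.argwhere(col == 0)[0][0])}")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("pearson_chi2", chi2, p, df=df, n=(int(obs.sum()),))


def fisher_exact_2x2(table) -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric point probabilities no larger than the
    observed table's (with a small relative slack against floating-point
    noise).  The reported statistic is the sample odds ratio.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0) or np.any(obs % 1 != 0):
        raise ValueError("fisher_exact_2x2 requires a 2x2 non-negative integer table")
    a, b = obs[0]
    c, d = obs[1]
    row1, col1, total = a + b, a + c, obs.sum()
    if min(row1, total - row1, col1, total - col1) == 0:
        raise ValueError("fisher_exact_2x2 requires all margins > 0")
    dist = sps.hypergeom(int(total), int(col1), int(row1))
    support = np.arange(
        max(0, int(row1 + col1 - total)), int(min(row1, col1)) + 1
    )
    pmf = dist.pmf(support)
    p_obs = dist.pmf(int(a))
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    odds = float(a * d / (b * c)) if b * c > 0 else float("inf")
    return TestResult("fisher_exact", odds, p, df=None, n=(int(total),))
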