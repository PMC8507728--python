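"""Nonparametric and exact tests shared by every pipeline stage.

Standard tests delegate to scipy/statsmodels/scikit-bio.  The r x c Fisher
exact test is implemented here (no Python library offers exact or
Monte-Carlo p-values beyond 2 x 2): exact enumeration of the table lattice
when it is small enough, otherwise seeded margin-preserving Monte Carlo.
The two-sided p-value follows the probability-at-most-observed rule: the
total null probability of margin-fixed tables no more probable than the
observed one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "friedman",
    "cochran_q",
    "mcnemar",
    "mann_whitney",
    "kruskal_wallis",
    "fisher_exact",
    "chi2_contingency",
    "benjamini_hochberg",
    "permanova",
]

# relative tolerance on the "probability at most observed" comparison,
# applied on the log scale (the convention of R's fisher.test)
_FISHER_REL_TOL = 1e-7


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: int | tuple
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def wilcoxon_signed_rank(diffs: np.ndarray, exact_limit: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical convention); tied absolute
    differences get average ranks.  The p-value is exact (enumeration of
    sign patterns) when the nonzero count is <= ``exact_limit`` and there
    are no ties, otherwise a normal approximation with continuity
    correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one paired difference")
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", 0)
    has_ties = np.unique(np.abs(nz)).size < n
    if n <= exact_limit and not has_ties:
        res = sps.wilcoxon(nz, method="exact", alternative="two-sided")
        method = "wilcoxon_signed_rank_exact"
    else:
        res = sps.wilcoxon(
            nz, method="approx", correction=True, alternative="two-sided"
        )
        method = "wilcoxon_signed_rank_normal"
    return TestResult(float(res.statistic), float(res.pvalue), method, n)


def friedman(blocks: np.ndarray) -> TestResult:
    """Friedman rank test on a subjects x conditions matrix.

    Tie-corrected chi-square statistic with df = k - 1.  Implemented
    directly (rather than via scipy) because the tie correction must also
    hold for k = 2 conditions, which scipy rejects; agreement with scipy for
    k >= 3 is covered by the test suite.
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x k matrix with k >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    colsum = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every row constant: no information
        return TestResult(0.0, 1.0, "friedman", n, {"df": k - 1})
    stat = (k - 1) * float(((colsum - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(stat, p, "friedman", n, {"df": k - 1})


def cochran_q(binary: np.ndarray) -> TestResult:
    """Cochran Q test on a subjects x k binary (presence/absence) matrix.

    Q = (k-1) [k Sum(C_j^2) - N^2] / (k N - Sum(R_i^2)), chi-square with
    k - 1 df.  Rows that are all-0 or all-1 carry no information; if every
    row is constant the test is degenerate and p = 1.
    """
    x = np.asarray(binary)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be 0/1")
    x = x.astype(float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need k >= 2 conditions")
    colsum = x.sum(axis=0)
    rowsum = x.sum(axis=1)
    total = x.sum()
    denom = k * total - float((rowsum**2).sum())
    if denom == 0:
        warnings.warn("all subjects constant across conditions; Q degenerate, p = 1")
        return TestResult(0.0, 1.0, "cochran_q", n, {"df": k - 1})
    q = (k - 1) * (k * float((colsum**2).sum()) - total**2) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult(q, p, "cochran_q", n, {"df": k - 1})


def mcnemar(a: np.ndarray, b: np.ndarray, exact: bool = True) -> TestResult:
    """McNemar test for two paired binary vectors (post-hoc for Cochran Q).

    ``exact=True`` uses the exact binomial distribution of the discordant
    pairs; otherwise the chi-square statistic without continuity correction
    (which for k = 2 equals Cochran's Q).
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    n01 = int(((a == 0) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    nd = n01 + n10
    if nd == 0:
        return TestResult(0.0, 1.0, "mcnemar", len(a), {"n01": n01, "n10": n10})
    if exact:
        p = float(sps.binomtest(min(n01, n10), nd, 0.5).pvalue)
        stat = float(min(n01, n10))
        method = "mcnemar_exact"
    else:
        stat = (n10 - n01) ** 2 / nd
        p = float(sps.chi2.sf(stat, 1))
        method = "mcnemar_chi2"
    return TestResult(stat, min(p, 1.0), method, len(a), {"n01": n01, "n10": n10})


def mann_whitney(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U test (unpaired); exact for small tie-free
    samples, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney", (a.size, b.size))


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group must be non-empty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(len(g) for g in groups))
    res = sps.kruskal(*groups)
    return TestResult(
        float(res.statistic), float(res.pvalue), "kruskal_wallis", tuple(len(g) for g in groups)
    )


# ---------------------------------------------------------------------------
# Fisher exact test for r x c tables
# ---------------------------------------------------------------------------


def _log_table_term(table: np.ndarray) -> float:
    """Sum of log(n_ij!) — the only table-dependent part of the null
    log-probability once margins are fixed."""
    return float(gammaln(table + 1.0).sum())


def _count_tables(rows: tuple, cols: tuple, cap: int) -> int | None:
    """Count margin-fixed tables by dynamic programming over column
    remainders.  Returns None if the state space or the count blows past
    ``cap`` (caller then falls back to Monte Carlo)."""
    states = {tuple(cols): 1}
    for r in rows[:-1]:
        new: dict = {}
        for st, cnt in states.items():
            for comp in _bounded_compositions(r, st):
                ns = tuple(s - v for s, v in zip(st, comp))
                new[ns] = new.get(ns, 0) + cnt
            if len(new) > 500_000:
                return None
        states = new
        if sum(states.values()) > cap * 10:
            return None
    return sum(states.values())


def _bounded_compositions(total: int, bounds: tuple):
    """All ways to write ``total`` as ordered non-negative parts with
    per-part upper bounds."""
    c = len(bounds)
    if c == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    lo = max(0, total - sum(bounds[1:]))
    hi = min(total, bounds[0])
    for v in range(lo, hi + 1):
        for rest in _bounded_compositions(total - v, bounds[1:]):
            yield (v,) + rest


def _fisher_exact_enumerate(rows, cols, s_obs: float) -> float:
    """Exact two-sided p by enumerating all tables with the given margins.

    Rows up to the antepenultimate are enumerated recursively; the
    penultimate row is vectorised and the last row is implied by the
    column remainders.
    """
    r = len(rows)
    logconst = (
        float(gammaln(np.add(rows, 1)).sum() + gammaln(np.add(cols, 1)).sum())
        - float(gammaln(sum(rows) + 1))
    )
    tol = np.log1p(_FISHER_REL_TOL)
    total_mass = 0.0
    extreme_mass = 0.0

    if r == 1:
        return 1.0

    def penultimate(colrem: tuple, s_partial: float):
        nonlocal total_mass, extreme_mass
        comps = np.array(list(_bounded_compositions(rows[r - 2], colrem)), dtype=float)
        if comps.size == 0:
            return
        last = np.asarray(colrem, dtype=float) - comps
        valid = (last >= 0).all(axis=1)
        comps, last = comps[valid], last[valid]
        if comps.size == 0:
            return
        s_tab = s_partial + gammaln(comps + 1).sum(axis=1) + gammaln(last + 1).sum(axis=1)
        mass = np.exp(logconst - s_tab)
        total_mass += float(mass.sum())
        extreme_mass += float(mass[s_tab >= s_obs - tol].sum())

    def recurse(i: int, colrem: tuple, s_partial: float):
        if i == r - 2:
            penultimate(colrem, s_partial)
            return
        for comp in _bounded_compositions(rows[i], colrem):
            ns = tuple(s - v for s, v in zip(colrem, comp))
            recurse(i + 1, ns, s_partial + float(gammaln(np.add(comp, 1)).sum()))

    recurse(0, tuple(cols), 0.0)
    # total_mass should be 1; normalise to absorb floating-point drift
    return min(1.0, extreme_mass / total_mass)


def _fisher_exact_montecarlo(rows, cols, s_obs: float, reps: int, seed) -> float:
    """Monte-Carlo two-sided p: sample margin-fixed tables row by row with
    (vectorised) sequential hypergeometric draws, which realises the null
    distribution given margins."""
    rng = np.random.default_rng(seed)
    r, c = len(rows), len(cols)
    colrem = np.tile(np.asarray(cols, dtype=np.int64), (reps, 1))
    s = np.zeros(reps)
    for i in range(r - 1):
        rowrem = np.full(reps, rows[i], dtype=np.int64)
        for j in range(c - 1):
            rest = colrem[:, j + 1 :].sum(axis=1)
            x = rng.hypergeometric(colrem[:, j], rest, rowrem)
            s += gammaln(x + 1.0)
            colrem[:, j] -= x
            rowrem -= x
        s += gammaln(rowrem + 1.0)
        colrem[:, c - 1] -= rowrem
    s += gammaln(colrem + 1.0).sum(axis=1)
    tol = np.log1p(_FISHER_REL_TOL)
    extreme = int((s >= s_obs - tol).sum())
    return (1 + extreme) / (1 + reps)


def fisher_exact(
    table: np.ndarray,
    mc_reps: int = 200_000,
    seed: int | None = 0,
    max_exact_tables: int = 10_000_000,
) -> TestResult:
    """Two-sided Fisher exact test on an r x c contingency table.

    Exact enumeration when the lattice of margin-fixed tables has at most
    ``max_exact_tables`` nodes, else Monte Carlo with ``mc_reps`` seeded
    margin-preserving draws and p = (1 + #extreme) / (1 + reps).  For 2 x 2
    tables the odds ratio is reported in ``extra``.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must contain non-negative integers")
    rows = tuple(int(x) for x in t.sum(axis=1))
    cols = tuple(int(x) for x in t.sum(axis=0))
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    extra: dict = {}
    if t.shape == (2, 2):
        a, b, c_, d = (float(x) for x in t.ravel())
        extra["odds_ratio"] = (a * d) / (b * c_) if b * c_ > 0 else np.inf
    if 0 in rows or 0 in cols:
        warnings.warn("table has a zero margin; degenerate p = 1")
        return TestResult(np.nan, 1.0, "fisher_exact_degenerate", n, extra)

    s_obs = _log_table_term(t.astype(float))
    n_tables = _count_tables(rows, cols, max_exact_tables)
    if n_tables is not None and n_tables <= max_exact_tables:
        p = _fisher_exact_enumerate(rows, cols, s_obs)
        method = "fisher_exact_enumeration"
        extra["n_tables"] = n_tables
    else:
        p = _fisher_exact_montecarlo(rows, cols, s_obs, mc_reps, seed)
        method = "fisher_exact_montecarlo"
        extra["mc_reps"] = mc_reps
    return TestResult(np.nan, float(min(p, 1.0)), method, n, extra)


def chi2_contingency(table: np.ndarray) -> TestResult:
    """Pearson chi-square test of independence on an r x c table, without
    continuity correction (the approximation classically reported for
    clinical contingency tables)."""
    t = np.asarray(table)
    res = sps.chi2_contingency(t, correction=False)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "pearson_chi2",
        int(t.sum()),
        {"df": int(res.dof)},
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permanova(
    distances,
    grouping,
    n_perm: int = 999,
    seed: int | None = 0,
) -> TestResult:
    """One-way PERMANOVA on a square distance matrix.

    Delegates the permutation test to scikit-bio; R-squared (among-group
    fraction of the total sum of squared distances) is computed from the
    distance partition and returned in ``extra``.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    d = np.asarray(distances, dtype=float)
    labels = np.asarray(grouping)
    if d.shape[0] != d.shape[1] or d.shape[0] != labels.size:
        raise ValueError("distance matrix and grouping sizes do not match")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")

    dm = DistanceMatrix(d, ids=[str(i) for i in range(d.shape[0])])
    res = skbio_permanova(dm, labels, permutations=n_perm, seed=seed)

    n = d.shape[0]
    ss_total = float((d[np.triu_indices(n, 1)] ** 2).sum()) / n
    ss_within = 0.0
    for g, cnt in zip(uniq, counts):
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += float((sub[np.triu_indices(cnt, 1)] ** 2).sum()) / cnt
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return TestResult(
        float(res["test statistic"]),
        float(res["p-value"]),
        "permanova",
        n,
        {"R2": r2, "n_perm": n_perm, "n_groups": int(uniq.size)},
    )
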