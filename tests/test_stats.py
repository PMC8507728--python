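"""Exact and nonparametric tests against enumeration oracles.

Every oracle here is an independent brute-force computation: sign-pattern
enumeration for the signed-rank test, within-row permutation for Friedman
and Cochran Q, assignment enumeration for Mann-Whitney and PERMANOVA, and
the closed-form hypergeometric sum for the 2 x 2 Fisher test.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import gammaln

from triomic.stats import (
    benjamini_hochberg,
    chi2_contingency,
    cochran_q,
    fisher_exact,
    friedman,
    kruskal_wallis,
    mann_whitney,
    mcnemar,
    permanova,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------- oracles


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all sign patterns."""
    d = diffs[diffs != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(ranks[np.array(signs, dtype=bool)].sum())
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n


def friedman_perm_p(blocks: np.ndarray) -> float:
    """Exact within-subject permutation p for the Friedman statistic
    (tie-free data): dynamic programming over the column rank sums, since
    the statistic depends on the rank matrix only through them."""
    obs = friedman(blocks).statistic
    n, k = blocks.shape
    row_perms = list(itertools.permutations(range(1, k + 1)))
    dist: dict[tuple, float] = {(0,) * k: 1.0}
    for _ in range(n):
        new: dict[tuple, float] = {}
        for state, prob in dist.items():
            for perm in row_perms:
                ns = tuple(s + r for s, r in zip(state, perm))
                new[ns] = new.get(ns, 0.0) + prob / len(row_perms)
        dist = new
    p = 0.0
    centre = n * (k + 1) / 2.0
    for state, prob in dist.items():
        stat = 12.0 / (n * k * (k + 1)) * sum((c - centre) ** 2 for c in state)
        if stat >= obs - 1e-12:
            p += prob
    return p


def cochran_perm_p(binary: np.ndarray) -> float:
    """Exact within-row permutation p for Cochran's Q: DP over column sums
    (row sums are invariant, so Q depends only on the column sums)."""
    obs = cochran_q(binary).statistic
    n, k = binary.shape
    dist: dict[tuple, float] = {(0,) * k: 1.0}
    for i in range(n):
        r = int(binary[i].sum())
        arrangements = list(itertools.combinations(range(k), r))
        new: dict[tuple, float] = {}
        for state, prob in dist.items():
            for pos in arrangements:
                ns = tuple(s + (j in pos) for j, s in enumerate(state))
                new[ns] = new.get(ns, 0.0) + prob / len(arrangements)
        dist = new
    rowsum = binary.sum(axis=1)
    total = float(binary.sum())
    denom = k * total - float((rowsum**2).sum())
    p = 0.0
    for state, prob in dist.items():
        q = (k - 1) * (k * sum(c**2 for c in state) - total**2) / denom
        if q >= obs - 1e-12:
            p += prob
    return p


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by enumerating all group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    na = a.size
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:na].sum()) - na * (na + 1) / 2
    mean_u = na * b.size / 2.0
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), na):
        u = float(ranks[list(idx)].sum()) - na * (na + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_2x2_closed_form(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2 x 2 table via the hypergeometric pmf."""
    a = table[0, 0]
    r1, r2 = table.sum(axis=1)
    c1 = table[:, 0].sum()
    n = table.sum()
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def permanova_f(d: np.ndarray, labels: np.ndarray) -> float:
    n = d.shape[0]
    groups = np.unique(labels)
    ss_t = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_w += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))


# ----------------------------------------------------------------- tests


class TestWilcoxonSignedRank:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.p_value == pytest.approx(0.0625)

    def test_all_zero(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank(np.zeros(6))
        assert res.p_value == 1.0

    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 8)
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(signed_rank_exact_p(d), abs=1e-12)


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = friedman(x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_k3(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        res = friedman(x)
        ref = sps.friedmanchisquare(*x.T)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_k2_agrees_with_sign_direction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 2))
        x[:, 1] += 2.0  # strong consistent direction
        res = friedman(x)
        assert res.p_value < 0.01

    def test_chi2_close_to_exact_permutation(self):
        # agreement is asserted in the decision-relevant tail; near p = 1
        # the exact permutation null is coarsely discrete and the
        # chi-square approximation is known to undershoot it there
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 3))
        x[:, 0] += 1.0
        approx = friedman(x).p_value
        exact = friedman_perm_p(x)
        assert approx == pytest.approx(exact, abs=0.02)


class TestCochranQ:
    def test_identical_columns(self):
        x = np.tile(np.array([[1], [0], [1], [1]]), (1, 3))
        with pytest.warns(UserWarning):
            res = cochran_q(x)
        assert res.p_value == 1.0

    def test_k2_equals_mcnemar_chi2(self):
        rng = np.random.default_rng(3)
        x = (rng.random((20, 2)) < 0.5).astype(int)
        q = cochran_q(x)
        m = mcnemar(x[:, 0], x[:, 1], exact=False)
        assert q.statistic == pytest.approx(m.statistic)
        assert q.p_value == pytest.approx(m.p_value)

    def test_statistic_formula(self):
        x = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [1, 0, 0], [1, 1, 1], [1, 0, 1]])
        col = x.sum(axis=0)
        row = x.sum(axis=1)
        k, n_total = 3, x.sum()
        expect = (k - 1) * (k * (col**2).sum() - n_total**2) / (k * n_total - (row**2).sum())
        assert cochran_q(x).statistic == pytest.approx(expect)

    def test_chi2_close_to_exact_permutation(self):
        rng = np.random.default_rng(4)
        x = (rng.random((15, 3)) < np.array([0.75, 0.45, 0.45])).astype(int)
        assert cochran_q(x).statistic > 0
        assert cochran_q(x).p_value == pytest.approx(cochran_perm_p(x), abs=0.05)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            cochran_q(np.array([[0, 2], [1, 0]]))


class TestMannWhitneyKruskal:
    def test_complete_separation(self):
        res = mann_whitney(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        # two-sided exact p = 2 * (1/20); one-sided 1/20 over C(6,3) splits
        assert res.p_value == pytest.approx(0.1)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.5, 1, 4)
        b = rng.normal(0.0, 1, 4)
        assert mann_whitney(a, b).p_value == pytest.approx(
            mannwhitney_exact_p(a, b), abs=1e-12
        )

    def test_identical_groups_p_near_one(self):
        a = np.arange(6.0)
        res = kruskal_wallis(a, a.copy())
        assert res.p_value > 0.9

    def test_kw_two_groups_consistent_with_mw(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1.2, 1, 15)
        p_kw = kruskal_wallis(a, b).p_value
        p_mw = mann_whitney(a, b).p_value
        assert (p_kw < 0.05) == (p_mw < 0.05)
        assert p_kw == pytest.approx(p_mw, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestFisherExact:
    def test_hand_enumeration_2x2(self):
        assert fisher_exact(np.array([[2, 0], [0, 2]])).p_value == pytest.approx(1 / 3)

    def test_proportional_rows(self):
        assert fisher_exact(np.array([[3, 3], [6, 6]])).p_value == pytest.approx(1.0)

    def test_2x2_matches_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(t).p_value == pytest.approx(
                fisher_2x2_closed_form(t), abs=1e-12
            )

    def test_row_col_permutation_invariance(self):
        t = np.array([[5, 1, 3], [2, 7, 4]])
        p0 = fisher_exact(t).p_value
        assert fisher_exact(t[::-1]).p_value == pytest.approx(p0, abs=1e-12)
        assert fisher_exact(t[:, ::-1]).p_value == pytest.approx(p0, abs=1e-12)
        assert fisher_exact(t.T).p_value == pytest.approx(p0, abs=1e-12)

    def test_rxc_enumeration_matches_reference(self):
        # frozen from R 4.3.3 fisher.test (exact, workspace enlarged)
        gender = np.array([[25, 33, 41], [21, 22, 36]])
        metastasis = np.array([[39, 46, 68], [7, 9, 9]])
        pn = np.array([[23, 36, 50], [13, 10, 23], [10, 9, 4]])
        assert fisher_exact(gender).p_value == pytest.approx(0.762709, abs=5e-7)
        assert fisher_exact(metastasis).p_value == pytest.approx(0.705452, abs=5e-7)
        assert fisher_exact(pn).p_value == pytest.approx(0.0319605, abs=5e-8)

    def test_montecarlo_agrees_with_exact(self):
        t = np.array([[23, 36, 50], [13, 10, 23], [10, 9, 4]])
        mc = fisher_exact(t, mc_reps=100_000, seed=11, max_exact_tables=10)
        assert mc.method == "fisher_exact_montecarlo"
        assert mc.p_value == pytest.approx(0.0319605, abs=3 * 6e-4)

    def test_montecarlo_reproducible(self):
        t = np.array([[8, 2, 5], [3, 9, 4], [4, 4, 9]])
        p1 = fisher_exact(t, mc_reps=20_000, seed=3, max_exact_tables=10).p_value
        p2 = fisher_exact(t, mc_reps=20_000, seed=3, max_exact_tables=10).p_value
        assert p1 == p2

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact(np.array([[0, 0], [3, 4]]))
        assert res.p_value == 1.0


def test_chi2_contingency_reference():
    # Pearson chi-square without correction; frozen from R chisq.test
    gender = np.array([[25, 33, 41], [21, 22, 36]])
    assert chi2_contingency(gender).p_value == pytest.approx(0.7286, abs=5e-5)


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])

    def test_dominates_input_and_matches_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        # independent step-up oracle
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        oracle_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestPermanova:
    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f_obs = permanova_f(d, labels)
        f_all = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            f_all.append(permanova_f(d, lab))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        res = permanova(d, labels, n_perm=49_999, seed=0)
        assert res.statistic == pytest.approx(f_obs, rel=1e-6)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_separated_blobs_min_p(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(d, labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)
        assert res.extra["R2"] > 0.9

    def test_null_labels_not_significant(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(20, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.array(["a", "b"] * 10)
        ps = [
            permanova(d, rng.permutation(labels), n_perm=199, seed=s).p_value
            for s in range(10)
        ]
        # under the null, p should behave uniformly: not all small
        assert np.median(ps) > 0.1
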