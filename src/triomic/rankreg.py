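"""Rank-based linear regression (Jaeckel dispersion, Wilcoxon scores) and
the drop-in-dispersion nested-model test.

The slope vector minimises the Jaeckel dispersion

    D(beta) = sum_i a(R(e_i)) e_i,   e = y - X beta,

with Wilcoxon scores a(i) = sqrt(12) (i/(n+1) - 1/2).  D is a convex,
piecewise-linear function of beta, invariant to adding a constant to y, so
the intercept is estimated separately as the median of the residuals.  The
drop-in-dispersion statistic for nested models,

    F = (RD / q) / (tau_hat / 2),  RD = D_reduced - D_full,

is referred to an F(q, n - p_full - 1) distribution, with tau estimated by
the Koul-Sievers-McKean window estimator (a uniform-kernel density estimate
of the pairwise residual-difference density at zero, bandwidth of order
n^(-1/5), degrees-of-freedom correction sqrt(n / (n - p - 1))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize

__all__ = ["wilcoxon_scores", "jaeckel_dispersion", "fit", "drop_in_dispersion", "RankFit", "DropTest"]


def wilcoxon_scores(n: int) -> np.ndarray:
    """Wilcoxon score vector a(i) = sqrt(12) (i/(n+1) - 1/2), i = 1..n.

    Sums to zero and is antisymmetric: a(i) = -a(n+1-i).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n + 1)
    return np.sqrt(12.0) * (i / (n + 1.0) - 0.5)


def _score_of_ranks(ranks: np.ndarray, n: int) -> np.ndarray:
    # average ranks from ties may be non-integer; the score formula extends
    # linearly, matching average scores over the tied block
    return np.sqrt(12.0) * (ranks / (n + 1.0) - 0.5)


def jaeckel_dispersion(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Jaeckel dispersion D(beta) with Wilcoxon scores; ties get average ranks."""
    e = y - x @ np.atleast_1d(beta)
    ranks = sps.rankdata(e)
    return float(np.sum(_score_of_ranks(ranks, e.size) * e))


@dataclass
class RankFit:
    """A fitted rank regression model."""

    beta: np.ndarray          # slope coefficients, clr units per covariate unit
    intercept: float          # median of residuals from the slope fit
    dispersion: float         # minimised D(beta_hat)
    tau: float                # KSM scale estimate (> 0)
    residuals: np.ndarray     # y - X beta_hat - intercept
    columns: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def n_params(self) -> int:
        return len(self.beta)


def _ksm_tau(residuals: np.ndarray, p: int, bandwidth_const: float = 1.0) -> float:
    """Koul-Sievers-McKean window estimate of tau.

    f(0) of the pairwise residual-difference density is estimated with a
    uniform kernel of half-width ``bandwidth_const * sigma * n^(-1/5)``
    (sigma = 1.483 MAD of the residuals); tau = 1 / (sqrt(12) f(0)),
    corrected by sqrt(n / (n - p - 1)).
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if n - p - 1 <= 0:
        raise ValueError("too few observations to estimate tau")
    sigma = 1.4826 * float(np.median(np.abs(e - np.median(e))))
    if sigma == 0:
        sigma = float(np.std(e))
    if sigma == 0:
        return np.finfo(float).tiny  # degenerate: all residuals equal
    h = bandwidth_const * sigma * n ** (-0.2)
    diffs = np.abs(e[:, None] - e[None, :])[np.triu_indices(n, 1)]
    m = int((diffs < h).sum())
    if m == 0:
        h = float(diffs[diffs > 0].min()) if (diffs > 0).any() else h
        m = max(int((diffs <= h).sum()), 1)
    f0 = m / (n * (n - 1) / 2.0) / (2.0 * h)
    tau = 1.0 / (np.sqrt(12.0) * f0)
    return float(tau * np.sqrt(n / (n - p - 1.0)))


def fit(
    x: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    n_restarts: int = 3,
    tol: float = 1e-8,
    seed: int = 0,
    bandwidth_const: float = 1.0,
) -> RankFit:
    """Fit a rank regression of ``y`` on design ``x`` (no intercept column).

    The dispersion is minimised with Nelder-Mead started at the
    least-squares solution plus ``n_restarts`` seeded jittered restarts
    (D is convex piecewise-linear; restarts guard against flat facets).
    An empty design (0 columns) yields the intercept-only null fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n != y.size:
        raise ValueError("x and y sizes disagree")
    if p > 0:
        if n <= p:
            raise ValueError(f"need n > p (n={n}, p={p})")
        xc = x - x.mean(axis=0)
        if np.linalg.matrix_rank(xc) < p:
            raise ValueError("design matrix is rank-deficient after centring")

    if columns is None:
        columns = [f"x{j}" for j in range(p)]

    if p == 0:
        beta = np.empty(0)
        disp = jaeckel_dispersion(np.zeros(0), x.reshape(n, 0), y)
        resid_slope = y.copy()
    else:
        rng = np.random.default_rng(seed)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        beta0, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        scale = np.maximum(np.abs(beta0), 1.0)
        best = None
        starts = [beta0] + [
            beta0 + rng.normal(0.0, 0.5, p) * scale for _ in range(n_restarts)
        ]
        for b0 in starts:
            res = minimize(
                jaeckel_dispersion,
                b0,
                args=(x, y),
                method="Nelder-Mead",
                options={"fatol": tol, "xatol": 1e-8, "maxiter": 4000 * p},
            )
            if best is None or res.fun < best.fun:
                best = res
        beta = np.atleast_1d(best.x)
        disp = float(best.fun)
        resid_slope = y - x @ beta

    intercept = float(np.median(resid_slope))
    residuals = resid_slope - intercept
    tau = _ksm_tau(residuals, p, bandwidth_const=bandwidth_const)
    return RankFit(
        beta=beta,
        intercept=intercept,
        dispersion=disp,
        tau=tau,
        residuals=residuals,
        columns=list(columns),
        n=n,
    )


@dataclass
class DropTest:
    """Drop-in-dispersion comparison of nested rank-regression fits."""

    reduction: float      # RD = D_reduced - D_full (>= 0 up to solver tolerance)
    df_num: int           # q = difference in model dimension
    df_den: int           # n - p_full - 1
    statistic: float      # F = (RD/q) / (tau_full/2)
    p_value: float


def drop_in_dispersion(full: RankFit, reduced: RankFit) -> DropTest:
    """Test the extra terms of ``full`` over ``reduced``.

    Requires the reduced model's columns to be a subset of the full model's
    columns (same response).  RD below zero by more than solver tolerance
    indicates a failed fit and raises.
    """
    if full.n != reduced.n:
        raise ValueError("models were fitted to different responses")
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("models are not nested")
    q = full.n_params - reduced.n_params
    if q == 0:
        return DropTest(0.0, 0, full.n - full.n_params - 1, 0.0, 1.0)
    rd = reduced.dispersion - full.dispersion
    if rd < -1e-6 * max(1.0, abs(full.dispersion)):
        raise ValueError(f"negative reduction in dispersion ({rd}); solver failure")
    rd = max(rd, 0.0)
    df_den = full.n - full.n_params - 1
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom")
    f_stat = (rd / q) / (full.tau / 2.0)
    p = float(sps.f.sf(f_stat, q, df_den))
    return DropTest(rd, q, df_den, f_stat, p)
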