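"""Joinpoint-style segmented log-linear trend fitting.

A joinpoint model describes ln(rate) as a continuous piecewise-linear
function of calendar year with k breakpoints ("joinpoints"). Following the
NCI grid-search convention, candidate joinpoints are restricted to observed
years, endpoints excluded, with a minimum of 2 observations between
consecutive joinpoints; for each k the placement minimizing the residual sum
of squares is found by exhaustive search. The number of joinpoints is chosen
by sequential Monte Carlo permutation tests (k vs k+1 at level alpha,
permuting residuals of the null fit); the Bayesian information criterion is
reported for every candidate k and used as a tie-breaker among placements.

Continuity at the joinpoints is obtained for free by parameterizing the mean
function with a truncated-line (hinge) basis: ln y = b0 + b1 t + sum_j g_j
(t - tau_j)_+, so each candidate placement is an ordinary least-squares fit.

Per-segment annual percent change is APC_j = (exp(slope_j) - 1) x 100; the
average annual percent change over a span is the duration-weighted geometric
mean, AAPC = (exp(sum_j w_j slope_j) - 1) x 100, with a delta-method CI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class JoinpointModel:
    """Fitted segmented trend for one rate series."""

    years: np.ndarray
    joinpoints: list[float]
    segment_slopes: np.ndarray
    slope_cov: np.ndarray
    apcs: list[dict]  # per segment: apc, ci_low, ci_high, start, end
    aapc: dict  # aapc, ci_low, ci_high, p_value over the full span
    n_segments: int
    bic: float
    bic_by_k: dict[int, float]
    rss: float
    permutation_p: float
    alpha: float
    coef: np.ndarray = field(repr=False, default=None)
    p_by_test: dict = field(repr=False, default_factory=dict)

    def predict(self, years) -> np.ndarray:
        """Fitted rate (not log-rate) at the given years."""
        X = _hinge_design(np.asarray(years, float), self.joinpoints)
        return np.exp(X @ self.coef)


def _hinge_design(t: np.ndarray, taus) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for tau in taus:
        cols.append(np.maximum(t - tau, 0.0))
    return np.column_stack(cols)


def _placements(n: int, k: int, min_gap: int) -> list[tuple[int, ...]]:
    """Index tuples of candidate joinpoints: endpoints excluded, gaps >= min_gap."""
    if k == 0:
        return [()]
    allowed = range(min_gap, n - min_gap)
    out = []
    for combo in itertools.combinations(allowed, k):
        if all(b - a >= min_gap for a, b in zip(combo, combo[1:])):
            out.append(combo)
    return out


def _fit_placement(t, lny, taus):
    X = _hinge_design(t, taus)
    coef, _, _, _ = np.linalg.lstsq(X, lny, rcond=None)
    resid = lny - X @ coef
    return coef, float(resid @ resid), X


def _best_fit(t, lny, placements):
    """Exhaustive search over placements; returns (taus, coef, rss, X)."""
    best = None
    for combo in placements:
        taus = [t[i] for i in combo]
        coef, rss, X = _fit_placement(t, lny, taus)
        if best is None or rss < best[2] - 1e-15:
            best = (taus, coef, rss, X)
    return best


def _min_rss_over_placements(Y: np.ndarray, hats: list[np.ndarray]) -> np.ndarray:
    """Column-wise min RSS of Y (n x B) over a list of hat matrices."""
    best = None
    for H in hats:
        R = Y - H @ Y
        rss = np.einsum("ij,ij->j", R, R)
        best = rss if best is None else np.minimum(best, rss)
    return best


def _bic(n: int, rss: float, k: int) -> float:
    # 2 + k regression coefficients plus k estimated breakpoint positions
    p = 2 + 2 * k
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + p * np.log(n)


def fit_joinpoint(
    years,
    values,
    max_joinpoints: int = 3,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    min_gap: int = 2,
) -> JoinpointModel:
    """Fit a segmented log-linear trend with a data-driven number of joinpoints.

    Parameters
    ----------
    years, values
        The rate series; values must be strictly positive.
    max_joinpoints
        Largest k considered (<= 4).
    n_perm
        Monte Carlo permutations per sequential test. 999 is a desk-scale
        default; the NCI tool uses 4499.
    alpha
        Level of each permutation test.
    seed
        Seed for the permutation RNG; fits are deterministic given it.
    min_gap
        Minimum number of observations between joinpoints (and between a
        joinpoint and either endpoint).
    """
    t = np.asarray(years, float)
    y = np.asarray(values, float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("years and values must be equal-length 1-D sequences")
    if not np.all(np.diff(t) > 0):
        raise ValueError("years must be strictly increasing")
    if (y <= 0).any():
        raise ValueError("joinpoint model is log-linear; rates must be positive")
    if not 0 <= max_joinpoints <= 4:
        raise ValueError("max_joinpoints must be between 0 and 4")
    n = len(t)
    lny = np.log(y)
    rng = np.random.default_rng(seed)

    placements_by_k = {k: _placements(n, k, min_gap) for k in range(max_joinpoints + 1)}
    feasible_k = max(k for k in placements_by_k if placements_by_k[k])
    if feasible_k < max_joinpoints and max_joinpoints > 0:
        warnings.warn(
            f"series of length {n} supports at most {feasible_k} joinpoints "
            f"(min_gap={min_gap}); reducing the search",
            stacklevel=2,
        )
        max_joinpoints = feasible_k

    # Sequential permutation tests: k vs k+1, stop at first non-rejection.
    k_sel = 0
    last_p = 1.0
    p_by_test: dict[tuple[int, int], float] = {}
    while k_sel < max_joinpoints:
        null = _best_fit(t, lny, placements_by_k[k_sel])
        alt = _best_fit(t, lny, placements_by_k[k_sel + 1])
        rss0, rss1 = null[2], alt[2]
        if rss0 <= 1e-14 * max(1.0, lny @ lny):
            last_p = 1.0
            break
        t_obs = rss0 / rss1 if rss1 > 0 else np.inf

        fitted0 = null[3] @ null[1]
        resid0 = lny - fitted0
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1).T  # (n, n_perm)
        Y = fitted0[:, None] + resid0[perm_idx]

        hats0 = [
            (lambda X: X @ np.linalg.pinv(X))(_hinge_design(t, [t[i] for i in c]))
            for c in placements_by_k[k_sel]
        ]
        hats1 = [
            (lambda X: X @ np.linalg.pinv(X))(_hinge_design(t, [t[i] for i in c]))
            for c in placements_by_k[k_sel + 1]
        ]
        rss0_star = _min_rss_over_placements(Y, hats0)
        rss1_star = _min_rss_over_placements(Y, hats1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(rss1_star > 0, rss0_star / rss1_star, np.inf)
        last_p = (1.0 + np.count_nonzero(t_star >= t_obs)) / (n_perm + 1.0)
        p_by_test[(k_sel, k_sel + 1)] = last_p
        if last_p < alpha:
            k_sel += 1
        else:
            break

    # BIC for every candidate k (best placement each), reported alongside.
    bic_by_k = {}
    best_by_k = {}
    for k in range(max_joinpoints + 1):
        best_by_k[k] = _best_fit(t, lny, placements_by_k[k])
        bic_by_k[k] = _bic(n, best_by_k[k][2], k)

    # p-value of the test that established the selected joinpoint count:
    # the rejection of k_sel-1 vs k_sel when k_sel > 0, else the first test.
    if k_sel > 0:
        perm_p = p_by_test[(k_sel - 1, k_sel)]
    else:
        perm_p = p_by_test.get((0, 1), 1.0)
    taus, coef, rss, X = best_by_k[k_sel]
    model = _finalize(t, lny, taus, coef, rss, X, bic_by_k, k_sel, perm_p, alpha)
    model.p_by_test = p_by_test
    return model


def _finalize(t, lny, taus, coef, rss, X, bic_by_k, k_sel, perm_p, alpha) -> JoinpointModel:
    n, p = X.shape
    dof = max(n - p, 1)
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov_coef = sigma2 * XtX_inv

    # slope of segment j = b1 + g_1 + ... + g_j  (linear map L on coefficients)
    k = len(taus)
    L = np.zeros((k + 1, p))
    L[:, 1] = 1.0
    for j in range(1, k + 1):
        L[j:, 1 + j] = 1.0
    slopes = L @ coef
    slope_cov = L @ cov_coef @ L.T

    bounds = [t[0], *taus, t[-1]]
    z = 1.96
    apcs = []
    for j, b in enumerate(slopes):
        se = float(np.sqrt(max(slope_cov[j, j], 0.0)))
        apcs.append(
            {
                "start": float(bounds[j]),
                "end": float(bounds[j + 1]),
                "apc": (np.exp(b) - 1.0) * 100.0,
                "ci_low": (np.exp(b - z * se) - 1.0) * 100.0,
                "ci_high": (np.exp(b + z * se) - 1.0) * 100.0,
                "slope": float(b),
                "se": se,
            }
        )

    model = JoinpointModel(
        years=t,
        joinpoints=[float(x) for x in taus],
        segment_slopes=slopes,
        slope_cov=slope_cov,
        apcs=apcs,
        aapc={},
        n_segments=k + 1,
        bic=bic_by_k[k_sel],
        bic_by_k=bic_by_k,
        rss=float(rss),
        permutation_p=float(perm_p),
        alpha=alpha,
        coef=coef,
    )
    model.aapc = aapc(model, (float(t[0]), float(t[-1])))
    return model


def aapc(model: JoinpointModel, year_range: tuple[float, float] | None = None) -> dict:
    """Average annual percent change over a span of the fitted range.

    AAPC = (exp(sum w_j * slope_j) - 1) x 100 with w_j the fraction of the
    span covered by segment j; CI and the two-sided p-value for AAPC = 0 come
    from the delta method on the segment-slope covariance.
    """
    t0, t1 = year_range if year_range is not None else (model.years[0], model.years[-1])
    lo, hi = float(model.years[0]), float(model.years[-1])
    t0, t1 = max(t0, lo), min(t1, hi)
    if t1 <= t0:
        raise ValueError("year_range does not overlap the fitted range")

    bounds = [lo, *model.joinpoints, hi]
    w = np.array(
        [
            max(0.0, min(t1, bounds[j + 1]) - max(t0, bounds[j]))
            for j in range(model.n_segments)
        ]
    )
    w = w / (t1 - t0)
    est = float(w @ model.segment_slopes)
    se = float(np.sqrt(max(w @ model.slope_cov @ w, 0.0)))
    z = 1.96
    if se > 0:
        p_value = float(2.0 * stats.norm.sf(abs(est) / se))
    else:
        p_value = 0.0 if est != 0 else 1.0
    return {
        "aapc": (np.exp(est) - 1.0) * 100.0,
        "ci_low": (np.exp(est - z * se) - 1.0) * 100.0,
        "ci_high": (np.exp(est + z * se) - 1.0) * 100.0,
        "p_value": p_value,
        "weights": w,
    }
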