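"""Hartigan's dip statistic and a Monte-Carlo unimodality test.

The dip D of a sample is the smallest sup-norm distance between the
empirical distribution function F_n and any unimodal distribution function
(convex up to some mode, concave beyond it, an atom at the mode allowed).

The implementation rests on a band/hull reduction.  Write the distinct
sorted values t_1 < ... < t_k with cumulative fractions F_i.  A unimodal G
with sup|F_n - G| <= d and mode at t_p exists iff

* left flank: the monotone greatest convex minorant H_L of the pre-jump
  staircase corners (t_i, F_{i-1}), i <= p, satisfies
  F_i - H_L(t_i) <= 2d for every i < p, and
* right flank: the monotone least concave majorant H_R of the post-jump
  corners (t_j, F_j), j >= p, satisfies H_R(t_j) - F_{j-1} <= 2d for j > p.

(The factor 2 appears because the hull of the d-shifted upper band must
stay above the d-shifted lower band.)  Mode placements between data points
are dominated by the adjacent point placements, so

    D = 1/2 * min_p max(Ldev(p), Rdev(p)),

floored at the conventional lower bound 1/(2n).  The Monte-Carlo p-value
compares D against dips of uniform(0, 1) samples of the same size,
Hartigan's conservative null choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _prepare(values) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if not np.isfinite(x).all():
        raise ValueError("dip statistic needs finite values")
    x = np.sort(x)
    t, counts = np.unique(x, return_counts=True)
    return t, np.cumsum(counts), x.size


def _left_deviations(t: np.ndarray, F_pre: np.ndarray, F_post: np.ndarray
                     ) -> np.ndarray:
    """Ldev(p) for p = 1..k: max_{i<p} (F_i - H_L^{(p)}(t_i)) where H_L^{(p)}
    is the lower convex hull of {(t_i, F_{i-1}) : i <= p}.  O(k^2) with an
    incremental Graham scan."""
    k = len(t)
    dev = np.zeros(k)
    hull: list[int] = []  # indices into t of hull vertices
    for p in range(k):
        # push point p = (t[p], F_pre[p]) keeping the lower hull convex
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            cross = (t[j] - t[i]) * (F_pre[p] - F_pre[i]) \
                - (F_pre[j] - F_pre[i]) * (t[p] - t[i])
            if cross < 0:  # j above the chord i--p: pop
                hull.pop()
            else:
                break
        hull.append(p)
        if p == 0:
            dev[p] = 0.0
            continue
        hx = t[hull]
        hy = F_pre[hull]
        hvals = np.interp(t[:p], hx, hy)
        dev[p] = float(np.max(F_post[:p] - hvals))
    return dev


def _vmin_all(t: np.ndarray, F_pre: np.ndarray, F_post: np.ndarray,
              d: float) -> np.ndarray:
    """Minimal feasible end value at t_p of a convex nondecreasing chain
    through the left bands [F_post - d, F_pre + d], for every p.

    Every feasible chain satisfies chain(t_i) >= l_i and, once the chord
    from an earlier upper bound (t_j, u_j) to (t_i, l_i) is positive,
    convexity forces all later slopes to at least that chord slope; the
    pointwise maximum of the resulting affine minorants is itself a valid
    chain, so the bound is attained.
    """
    k = len(t)
    lo = F_post - d
    up = F_pre + d
    vmin = np.zeros(k)
    if k == 1:
        return vmin
    dt = t[:, None] - t[None, :]                       # t_i - t_j
    with np.errstate(divide="ignore", invalid="ignore"):
        chord = (lo[:, None] - up[None, :]) / dt       # slope forced by (j, i)
    chord = np.where(np.tril(np.ones((k, k), dtype=bool), -1), chord, -np.inf)
    s = np.maximum(chord.max(axis=1), 0.0)             # forced slope after t_i
    s = np.maximum.accumulate(s)
    # v_min(p) = max_{i<p} [ lo_i + s_i (t_p - t_i) ], at least 0
    aff = lo[None, :] + s[None, :] * (t[:, None] - t[None, :])  # (p, i)
    aff = np.where(np.tril(np.ones((k, k), dtype=bool), -1), aff, -np.inf)
    return np.maximum(aff.max(axis=1), 0.0)


def _feasible(t, F_pre, F_post, ldev, rdev, d: float) -> bool:
    """Is there a mode placement admitting a unimodal G within sup-distance
    d of the ECDF?  Combines flank feasibility with the junction condition
    v_min(p) <= min(u_max(p), F(t_p) + d)."""
    vmin = _vmin_all(t, F_pre, F_post, d)
    # u_max via reflection (x -> -x, F -> 1 - F)
    vref = _vmin_all(-t[::-1], (1.0 - F_post)[::-1], (1.0 - F_pre)[::-1], d)[::-1]
    umax = np.minimum(1.0 - vref, F_post + d)
    ok = (ldev <= 2 * d + 1e-15) & (rdev <= 2 * d + 1e-15) \
        & (vmin <= umax + 1e-15)
    return bool(ok.any())


def dip_statistic(values) -> float:
    """Hartigan's dip of a sample (n >= 4); affine-invariant, in
    [1/(2n), 1/4]."""
    t, cum, n = _prepare(values)
    k = len(t)
    F_post = cum / n                      # F(t_i)
    F_pre = np.concatenate([[0.0], F_post[:-1]])  # F(t_i^-)
    if k == 1:
        return 1.0 / (2 * n)
    t = (t - t[0]) / (t[-1] - t[0])       # affine-invariant scale
    ldev = _left_deviations(t, F_pre, F_post)
    rdev = _left_deviations(-t[::-1], (1.0 - F_post)[::-1], (1.0 - F_pre)[::-1])[::-1]
    lo = float(np.min(np.maximum(ldev, rdev))) / 2.0  # junction-free bound
    hi = 0.251
    if _feasible(t, F_pre, F_post, ldev, rdev, lo):
        return max(lo, 1.0 / (2 * n))
    while hi - lo > 5e-14:
        mid = 0.5 * (lo + hi)
        if _feasible(t, F_pre, F_post, ldev, rdev, mid):
            hi = mid
        else:
            lo = mid
    return max(hi, 1.0 / (2 * n))


@dataclass
class DipTestResult:
    statistic: float
    n: int
    p_value: float
    n_null: int
    seed: int | None
    low_replicates: bool = False


def null_dip_distribution(n: int, n_null: int = 9999,
                          seed: int | None = 0) -> np.ndarray:
    """Dips of ``n_null`` uniform(0, 1) samples of size *n* (the Monte-Carlo
    null reference); reusable across tests at the same sample size."""
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_null)])


def dip_pvalue(statistic: float, n: int, n_null: int = 9999,
               seed: int | None = 0,
               null_dips: np.ndarray | None = None) -> DipTestResult:
    """Monte-Carlo p-value: p = (1 + #{D* >= D}) / (n_null + 1) with D* the
    dips of uniform null samples of size *n*.  A precomputed ``null_dips``
    array may be supplied to share the reference across many tests."""
    if null_dips is None:
        null_dips = null_dip_distribution(n, n_null=n_null, seed=seed)
    m = len(null_dips)
    p = (1 + int(np.sum(null_dips >= statistic - 1e-15))) / (m + 1)
    return DipTestResult(statistic, n, p, m, seed, low_replicates=m < 99)


def dip_test(values, n_null: int = 9999, seed: int | None = 0,
             null_dips: np.ndarray | None = None) -> DipTestResult:
    """Dip statistic plus its Monte-Carlo p-value in one call."""
    d = dip_statistic(values)
    n = len(np.asarray(values).ravel())
    return dip_pvalue(d, n, n_null=n_null, seed=seed, null_dips=null_dips)
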