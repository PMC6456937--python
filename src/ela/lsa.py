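"""Local similarity analysis: signed local-similarity statistic, p-values and
the all-pairs co-occurrence screen.

The local similarity (LS) score of two normalized series is the maximal
absolute segment sum of their elementwise products, divided by the *full*
series length n, maximized over alignment offsets d with |d| <= D.  It is a
local analogue of a correlation coefficient: associations confined to part of
a time series still produce a large score.  The positive accumulator captures
co-varying segments, the negative accumulator anti-varying segments.

Significance. The maximal absolute segment sum equals the range (max minus
min) of the partial-sum walk of the products, so sqrt(n) * LS converges under
the null to the range of a standard Brownian motion on [0, 1], whose tail has
the rapidly converging reflection series

    P(R >= x) = 8 * sum_{k>=1} (-1)^(k-1) * k * (1 - Phi(k*x)).

At realistic n this asymptotic tail is visibly anticonservative, so the
default theoretical p-value evaluates a precomputed finite-sample calibration
surface of the exact rank-score permutation null (simulated once offline at
high precision over a grid of series lengths, in the same spirit as the
response-surface p-values used for the Lilliefors and Dickey-Fuller tests)
and falls back to the reflection series beyond the tabulated range.  The
theoretical p-value is validated against the permutation test in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from . import _null_table
from .fdr import storey_qvalues
from .normalize import NormalizedSeries
from .util import spawn_rng

P_METHODS = ("theo", "perm")


@dataclass
class PairAssociation:
    """One screened pair: signed LS score, optimal segment, delay, p and q."""

    x_id: str
    y_id: str
    ls: float                 # signed LS score
    interval_start: int       # 1-based inclusive, in x-series coordinates
    interval_end: int
    delay: int
    p: float
    q: float = float("nan")

    @property
    def sign(self) -> str:
        return "-" if self.ls < 0 else "+"

    @property
    def span(self) -> int:
        return self.interval_end - self.interval_start + 1


def _as_array(series) -> np.ndarray:
    if isinstance(series, NormalizedSeries):
        return series.z
    return np.asarray(series, dtype=float)


def _offset_order(max_delay: int):
    """Offsets in tie-break order: smaller |d| first, negative before positive."""
    order = [0]
    for a in range(1, max_delay + 1):
        order.extend([-a, a])
    return order


def _dp_one_offset(zx: np.ndarray, zy: np.ndarray, d: int, refine: bool = True):
    """Best positive and negative segment for one alignment offset.

    Pairs zx[i] with zy[i + d]; returns two candidates
    (score, sign, start, end) with 0-based inclusive x-coordinates.

    The accumulator scan finds the maximal score; a second pass then finds
    the earliest-start, then shortest, segment attaining that exact score.
    The pass is needed because normal scores contain exactly antisymmetric
    values, so a maximal segment can be tied by extending it backwards over
    a chunk whose running sum is exactly zero -- a candidate the plain
    maximal-segment recursion never visits.
    """
    n = zx.size
    i0 = max(0, -d)
    i1 = n - 1 - max(0, d)
    prod = zx[i0:i1 + 1] * zy[i0 + d:i1 + d + 1]
    out = []
    for sgn in (1.0, -1.0):
        acc = 0.0
        best = 0.0
        best_start = best_end = 0
        start = 0
        for k, s in enumerate(prod):
            acc += sgn * s
            if acc < 0.0:
                acc = 0.0
                start = k + 1
            elif acc > best:
                best = acc
                best_start, best_end = start, k
        if refine and best > 0.0:
            best_start, best_end = _earliest_tied_segment(prod, sgn, best)
        out.append((best, "+" if sgn > 0 else "-", i0 + best_start, i0 + best_end))
    return out


def _earliest_tied_segment(prod: np.ndarray, sgn: float, target: float):
    """Earliest-start, then shortest, segment whose left-to-right running
    sum equals ``target`` exactly (the DP maximum is always attainable)."""
    for a in range(prod.size):
        acc = 0.0
        for b in range(a, prod.size):
            acc += sgn * prod[b]
            if acc == target:
                return a, b
    raise AssertionError("unreachable: DP maximum not found in refinement")


def local_similarity(zx, zy, max_delay: int = 0):
    """Signed LS score with the optimal segment and delay.

    Returns ``(ls, sign, (interval_start, interval_end), delay)`` where the
    interval is 1-based inclusive in x-series coordinates and ``ls`` carries
    the sign.  Ties are broken deterministically: positive over negative
    accumulator, then smaller |delay| (negative offset first), then earliest
    segment start, then shortest segment.
    """
    zx = _as_array(zx)
    zy = _as_array(zy)
    if zx.size != zy.size:
        raise ValueError(f"series lengths differ ({zx.size} vs {zy.size})")
    n = zx.size
    if n < 2:
        raise ValueError("series must have length >= 2")
    if max_delay < 0 or max_delay >= n:
        raise ValueError("max_delay must satisfy 0 <= D < n")

    best = None
    best_key = None
    for d in _offset_order(max_delay):
        for score, sign, s0, e0 in _dp_one_offset(zx, zy, d):
            # lower key wins; mirrors the documented tie-break chain
            key = (-score, 0 if sign == "+" else 1, abs(d),
                   0 if d < 0 else 1, s0, e0 - s0)
            if best_key is None or key < best_key:
                best_key = key
                best = (score, sign, s0, e0, d)
    score, sign, s0, e0, d = best
    ls = score / n if sign == "+" else -score / n
    return ls, sign, (s0 + 1, e0 + 1), d


def _range_stat(products_2d: np.ndarray) -> np.ndarray:
    """Max absolute segment sum for each row of products (vectorized DP)."""
    s = np.cumsum(products_2d, axis=-1)
    hi = np.maximum(s.max(axis=-1), 0.0)
    lo = np.minimum(s.min(axis=-1), 0.0)
    return hi - lo


def ls_magnitude(zx, zy, max_delay: int = 0) -> float:
    """|LS| only (no interval recovery); matches ``local_similarity``."""
    zx = _as_array(zx)
    zy = _as_array(zy)
    n = zx.size
    best = 0.0
    for d in _offset_order(max_delay):
        i0 = max(0, -d)
        i1 = n - 1 - max(0, d)
        prod = zx[i0:i1 + 1] * zy[i0 + d:i1 + d + 1]
        best = max(best, float(_range_stat(prod[None, :])[0]))
    return best / n


# ---------------------------------------------------------------------------
# theoretical p-value
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _score_variance(n: int) -> float:
    """Mean squared normal score Phi^-1(k/(n+1)), k=1..n (slightly below 1)."""
    sc = norm.ppf(np.arange(1, n + 1) / (n + 1))
    return float(np.mean(sc ** 2))


def brownian_range_tail(x: float) -> float:
    """Asymptotic tail of the range of standard Brownian motion on [0, 1]."""
    if x <= 0:
        return 1.0
    t = 0.0
    for k in range(1, 400):
        term = 8.0 * (-1) ** (k - 1) * k * norm.sf(k * x)
        t += term
        if abs(term) < 1e-16 and k > 3:
            break
    return float(min(1.0, max(0.0, t)))


# interpolation axes: u = 1/sqrt(n), with u = 0 holding the asymptotic column
_U_GRID = np.concatenate([[0.0], 1.0 / np.sqrt(_null_table.N_GRID[::-1].astype(float))])
_LN_TAIL = np.vstack([_null_table.LN_TAIL_ASYM, _null_table.LN_TAIL[::-1]])
_X_GRID = _null_table.X_GRID
_N_MIN = int(_null_table.N_GRID.min())


def _ln_tail_at(x: float, lnp_col: np.ndarray) -> float:
    if x <= 0:
        return 0.0
    if x >= _X_GRID[-1]:
        # far tail: continue with the reflection series, offset-matched
        return float(lnp_col[-1]
                     + np.log(max(brownian_range_tail(x), 1e-300))
                     - np.log(max(brownian_range_tail(_X_GRID[-1]), 1e-300)))
    # linear in ln p between grid points (x=0 -> ln p = 0)
    xs = np.concatenate([[0.0], _X_GRID])
    ys = np.concatenate([[0.0], lnp_col])
    return float(np.interp(x, xs, ys))


def theoretical_pvalue(ls: float, n: int, max_delay: int = 0) -> float:
    """Theoretical p-value of an |LS| score for series of length n.

    Standardizes x = |LS| * sqrt(n) / s2_n (s2_n the mean squared normal
    score) and evaluates the precomputed finite-sample null surface,
    interpolating linearly in (1/sqrt(n), x) of the log tail; beyond the
    tabulated grid the Brownian-range reflection series takes over.  Offsets
    for D > 0 are combined as 1 - F(x)^(2D+1), treating them as approximately
    independent.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if max_delay < 0:
        raise ValueError("max_delay must be >= 0")
    x = abs(float(ls)) * np.sqrt(n) / _score_variance(max(n, 2))
    if x == 0.0:
        return 1.0
    u = 1.0 / np.sqrt(n)
    u = min(u, 1.0 / np.sqrt(_N_MIN))  # clamp below n=15 to the shortest column
    j = int(np.searchsorted(_U_GRID, u, side="right"))
    j = min(max(j, 1), _U_GRID.size - 1)
    lo, hi = _U_GRID[j - 1], _U_GRID[j]
    w = 0.0 if hi == lo else (u - lo) / (hi - lo)
    lnp = (1.0 - w) * _ln_tail_at(x, _LN_TAIL[j - 1]) + w * _ln_tail_at(x, _LN_TAIL[j])
    p0 = float(np.exp(lnp))
    p0 = min(1.0, max(p0, 0.0))
    if max_delay == 0:
        return p0
    return float(-np.expm1((2 * max_delay + 1) * np.log1p(-min(p0, 1 - 1e-16))))


def ls_score_cutoff(n: int, p_cut: float = 0.001, max_delay: int = 0,
                    grid: float = 0.01) -> float:
    """Smallest LS score on a ``grid``-spaced scale with p <= p_cut."""
    ls = grid
    while ls < 10.0:
        if theoretical_pvalue(ls, n, max_delay) <= p_cut:
            return round(ls, 10)
        ls = round(ls + grid, 10)
    raise RuntimeError("no LS score on the grid reached the requested p-value")


# ---------------------------------------------------------------------------
# permutation p-value
# ---------------------------------------------------------------------------

def permutation_pvalue_ls(zx, zy, n_perm: int = 1000, seed=None,
                          max_delay: int = 0, observed: float | None = None) -> float:
    """Permutation p-value for |LS|: permute one series, recompute, count.

    p = (1 + #{|LS_perm| >= |LS_obs|}) / (n_perm + 1).  ``observed`` (an |LS|
    value) can be supplied to reuse a precomputed statistic.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    zx = _as_array(zx)
    zy = _as_array(zy)
    n = zx.size
    obs = ls_magnitude(zx, zy, max_delay) if observed is None else abs(observed)
    rng = spawn_rng(seed)
    perm_stats = np.zeros(n_perm)
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        idx = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        zyp = zy[idx]
        best = np.zeros(m)
        for d in _offset_order(max_delay):
            i0 = max(0, -d)
            i1 = n - 1 - max(0, d)
            prod = zx[i0:i1 + 1] * zyp[:, i0 + d:i1 + d + 1]
            np.maximum(best, _range_stat(prod), out=best)
        perm_stats[start:start + m] = best / n
    return float((1 + np.sum(perm_stats >= obs - 1e-12)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# all-pairs screen
# ---------------------------------------------------------------------------

def screen_pairs(normalized: dict[str, NormalizedSeries],
                 p_cut: float = 0.001, q_cut: float = 0.05,
                 min_span_fraction: float = 0.5, max_delay: int = 0,
                 p_method: str = "theo", n_perm: int = 1000,
                 seed=None) -> list[PairAssociation]:
    """Screen all unordered factor pairs for significant local associations.

    Keeps pairs with p <= p_cut, q <= q_cut (q over the family of all tested
    pairs) and an optimal segment spanning strictly more than
    ``min_span_fraction`` of the series.  Returns survivors sorted by
    (p, -|LS|, ids).
    """
    if p_method not in P_METHODS:
        raise ValueError(f"p_method must be one of {P_METHODS}")
    ids = list(normalized)
    if len(ids) < 2:
        raise ValueError("need at least two factors to screen pairs")
    n = len(normalized[ids[0]].z)
    for fid in ids:
        if len(normalized[fid].z) != n:
            raise ValueError(f"factor {fid!r} has a different series length")

    # score every pair (magnitudes only -- intervals are recovered later,
    # and only for pairs that survive the p/q filters)
    pair_ids = [(xi, yi) for i, xi in enumerate(ids) for yi in ids[i + 1:]]
    magnitudes = np.array([
        ls_magnitude(normalized[xi], normalized[yi], max_delay)
        for xi, yi in pair_ids
    ])
    if p_method == "theo":
        pvals = np.array([theoretical_pvalue(m, n, max_delay) for m in magnitudes])
    else:
        pvals = np.array([
            permutation_pvalue_ls(
                normalized[xi], normalized[yi], n_perm=n_perm,
                seed=spawn_rng(seed, "ls", xi, yi), max_delay=max_delay,
                observed=m,
            )
            for (xi, yi), m in zip(pair_ids, magnitudes)
        ])

    fam = storey_qvalues(pvals)
    survivors = []
    for (xi, yi), p, q in zip(pair_ids, fam.p, fam.q):
        if p > p_cut or q > q_cut:
            continue
        ls, _, (a, b), d = local_similarity(normalized[xi], normalized[yi],
                                            max_delay)
        pair = PairAssociation(x_id=xi, y_id=yi, ls=ls, interval_start=a,
                               interval_end=b, delay=d, p=float(p), q=float(q))
        if pair.span > min_span_fraction * n:
            survivors.append(pair)
    survivors.sort(key=lambda a: (a.p, -abs(a.ls), a.x_id, a.y_id))
    return survivors
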