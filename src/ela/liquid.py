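"""Liquid association: third-party mediation of screened pairs.

For a screened pair (X, Y) and a candidate mediator Z, all on the normal-score
scale, the liquid association score is the sample third moment

    LA(X; Y | Z) = (1/m) * sum_i x_i y_i z_i,

an estimate of E(XYZ).  Because the scores are centered, LA weights the XY
co-variation by the level of Z: positive LA means X and Y co-vary most
strongly where Z is high, negative LA where Z is low.  The score is fully
symmetric in its three arguments; it is the screening step (which fixes the
correlated pair) that designates Z as the mediator.

Combining the sign of the pair's LS score with the sign of LA yields the four
mediated-correlation types:

    A  (+, +)  high Z enhances a positive X-Y correlation
    B  (-, +)  low  Z enhances a negative X-Y correlation
    C  (+, -)  low  Z enhances a positive X-Y correlation
    D  (-, -)  high Z enhances a negative X-Y correlation

Significance is assessed by permuting Z only (the pair's own dependence
structure is preserved), two-sided by default since both LA signs are
meaningful; a one-sided option tests for mediators that enhance where they
are high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdr import storey_qvalues
from .lsa import PairAssociation
from .normalize import NormalizedSeries
from .util import spawn_rng

LA_TYPES = ("A", "B", "C", "D")


@dataclass
class TripletAssociation:
    """One mediated triplet: the pair (X, Y), mediator Z, LA score and type."""

    x_id: str
    y_id: str
    z_id: str
    la: float
    m: int
    p: float
    q: float = float("nan")
    la_type: str = ""
    pair_ls_sign: str = "+"


def _arr(series) -> np.ndarray:
    if isinstance(series, NormalizedSeries):
        return series.z
    return np.asarray(series, dtype=float)


def la_score(zx, zy, zz) -> float:
    """Mean elementwise triple product; symmetric in all three arguments."""
    x, y, z = _arr(zx), _arr(zy), _arr(zz)
    if not (x.size == y.size == z.size):
        raise ValueError(
            f"series lengths differ ({x.size}, {y.size}, {z.size})"
        )
    if x.size < 1:
        raise ValueError("series must be non-empty")
    # multiply each triple in a canonical order so the score is exactly
    # (not just up to rounding) symmetric in its three arguments
    stacked = np.sort(np.vstack([x, y, z]), axis=0)
    return float(np.mean(stacked[0] * stacked[1] * stacked[2]))


def la_permutation_test(zx, zy, zz, n_perm: int = 1000, seed=None,
                        one_sided: bool = False,
                        observed: float | None = None) -> float:
    """Permutation p-value for LA: permute Z only, recompute, count.

    Two-sided (default): p = (1 + #{|LA_perm| >= |LA_obs|}) / (n_perm + 1).
    One-sided: counts permuted scores >= the observed score.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, y, z = _arr(zx), _arr(zy), _arr(zz)
    m = x.size
    obs = la_score(x, y, z) if observed is None else observed
    # LA depends only on the pairing of the xy products with z, so both are
    # put into canonical (sorted) order before drawing random pairings; the
    # p-value is then exactly invariant under jointly permuting (x, y, z)
    xy = np.sort(x * y)
    zs = np.sort(z)
    rng = spawn_rng(seed)
    count = 0
    chunk = max(1, int(4e6 // max(m, 1)))
    for start in range(0, n_perm, chunk):
        k = min(chunk, n_perm - start)
        idx = rng.permuted(np.tile(np.arange(m), (k, 1)), axis=1)
        la_perm = zs[idx] @ xy / m
        if one_sided:
            count += int(np.sum(la_perm >= obs - 1e-12))
        else:
            count += int(np.sum(np.abs(la_perm) >= abs(obs) - 1e-12))
    return float((1 + count) / (n_perm + 1))


def classify_la_type(pair_ls_sign: str, la_sign: str) -> str:
    """Map (sign of the pair's LS, sign of LA) to the mediation type A-D."""
    key = (pair_ls_sign, la_sign)
    table = {("+", "+"): "A", ("-", "+"): "B", ("+", "-"): "C", ("-", "-"): "D"}
    if key not in table:
        raise ValueError(
            f"signs must be '+' or '-', got {pair_ls_sign!r}, {la_sign!r} "
            "(zero-LA triplets are never classified)"
        )
    return table[key]


def scan_mediators(pair: PairAssociation,
                   normalized: dict[str, NormalizedSeries],
                   n_perm: int = 1000, p_cut: float = 0.001,
                   q_cut: float = 0.05, la_effect_cut: float | None = None,
                   seed=None, one_sided: bool = False,
                   return_all: bool = False) -> list[TripletAssociation]:
    """Evaluate every factor other than X and Y as a mediator of the pair.

    When called standalone the q-values are computed over this pair's own
    candidate family and the p/q/effect filters are applied.  The pipeline
    instead calls ``scan_all_mediators`` to pool the q-value family across
    all screened pairs before filtering (``return_all=True`` returns the
    unfiltered scan for that purpose).
    """
    x = normalized[pair.x_id].z
    y = normalized[pair.y_id].z
    xy = x * y
    m = xy.size
    triplets = []
    for z_id, series in normalized.items():
        if z_id in (pair.x_id, pair.y_id):
            continue
        la = float(series.z @ xy / m)
        p = la_permutation_test(
            x, y, series.z, n_perm=n_perm,
            seed=spawn_rng(seed, "la", pair.x_id, pair.y_id, z_id),
            one_sided=one_sided, observed=la,
        )
        la_sign = "+" if la > 0 else ("-" if la < 0 else "")
        triplets.append(TripletAssociation(
            x_id=pair.x_id, y_id=pair.y_id, z_id=z_id, la=la, m=m, p=p,
            la_type=classify_la_type(pair.sign, la_sign) if la_sign else "",
            pair_ls_sign=pair.sign,
        ))
    if return_all:
        return triplets
    fam = storey_qvalues(np.array([t.p for t in triplets]))
    for t, q in zip(triplets, fam.q):
        t.q = float(q)
    return _filter_triplets(triplets, p_cut, q_cut, la_effect_cut)


def _filter_triplets(triplets, p_cut, q_cut, la_effect_cut):
    out = [
        t for t in triplets
        if t.p <= p_cut and t.q <= q_cut
        and (la_effect_cut is None or abs(t.la) >= la_effect_cut)
    ]
    out.sort(key=lambda t: (t.p, -abs(t.la), t.x_id, t.y_id, t.z_id))
    return out


def scan_all_mediators(pairs: list[PairAssociation],
                       normalized: dict[str, NormalizedSeries],
                       n_perm: int = 1000, p_cut: float = 0.001,
                       q_cut: float = 0.05, la_effect_cut: float | None = None,
                       seed=None, one_sided: bool = False):
    """Mediator scan over all screened pairs with one pooled q-value family.

    Returns ``(survivors, n_tested)`` where ``n_tested`` is the total number
    of (pair, Z) tests in the pooled family.
    """
    all_triplets: list[TripletAssociation] = []
    for pair in pairs:
        all_triplets.extend(scan_mediators(
            pair, normalized, n_perm=n_perm, seed=seed,
            one_sided=one_sided, return_all=True,
        ))
    if not all_triplets:
        return [], 0
    fam = storey_qvalues(np.array([t.p for t in all_triplets]))
    for t, q in zip(all_triplets, fam.q):
        t.q = float(q)
    return _filter_triplets(all_triplets, p_cut, q_cut, la_effect_cut), len(all_triplets)
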