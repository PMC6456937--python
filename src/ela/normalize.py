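"""Missing-value imputation and the rank-based inverse-normal transformation.

Every factor series is replaced by its normal scores

    Z_k = Phi^{-1}( R_k / (n + 1) ),

where R_k is the (mid)rank of X_k among the n observations and Phi is the
standard normal CDF.  The transform is invariant to strictly increasing
re-expressions of the raw data, which makes the downstream local-similarity
and liquid-association scores behave like correlation-scale statistics and
accommodates strongly skewed relative abundances.

Note that the sample variance of normal scores is below one (it converges to
one as n grows); the scores are deliberately not rescaled, and the null
calibration of the local-similarity p-value accounts for this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

IMPUTE_METHODS = ("linear", "zero", "fail")


@dataclass
class NormalizedSeries:
    """Normal scores of one factor series: z_k = Phi^-1(R_k/(n+1))."""

    factor_id: str
    z: np.ndarray
    ranks: np.ndarray

    def __len__(self) -> int:
        return self.z.size


def impute_missing(series: np.ndarray, method: str = "linear",
                   factor_id: str = "<series>") -> np.ndarray:
    """Fill missing (NaN) values of a 1-d series.

    ``linear``
        straight-line interpolation in time between the nearest observed
        neighbours; leading/trailing gaps are filled with the nearest
        observed value.
    ``zero``
        missing values become 0.
    ``fail``
        raise if any value is missing.
    """
    if method not in IMPUTE_METHODS:
        raise ValueError(f"unknown imputation method {method!r}")
    x = np.asarray(series, dtype=float).copy()
    miss = np.isnan(x)
    if not miss.any():
        return x
    if method == "fail":
        raise ValueError(f"factor {factor_id!r} has missing values (method='fail')")
    if method == "zero":
        x[miss] = 0.0
        return x
    obs = np.flatnonzero(~miss)
    if obs.size == 0:
        raise ValueError(f"factor {factor_id!r} is entirely missing")
    # np.interp clamps to the nearest observed value outside the observed span
    x[miss] = np.interp(np.flatnonzero(miss), obs, x[obs])
    return x


def rank_normal_transform(x: np.ndarray, factor_id: str = "<series>") -> NormalizedSeries:
    """Rank-based inverse-normal transform with midranks for ties.

    A constant series maps to all-zero scores (it carries no association
    signal); a warning is logged in that case.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("input must be a non-empty 1-d vector")
    if np.isnan(x).any():
        raise ValueError(f"factor {factor_id!r} still has missing values; impute first")
    n = x.size
    ranks = rankdata(x, method="average")
    z = norm.ppf(ranks / (n + 1))
    if np.ptp(x) == 0 and n > 1:
        logger.warning("factor %r is constant; its normal scores are all zero", factor_id)
    return NormalizedSeries(factor_id=factor_id, z=z, ranks=ranks)


def normalize_table(table, impute_method: str = "linear") -> dict[str, NormalizedSeries]:
    """Impute then rank-normalize every factor row of an AbundanceTable.

    The same normalized scores feed both the local-similarity screen and the
    liquid-association scan.
    """
    out: dict[str, NormalizedSeries] = {}
    for fid in table.factor_ids:
        row = table.values.loc[fid].to_numpy(dtype=float)
        try:
            filled = impute_missing(row, method=impute_method, factor_id=fid)
            out[fid] = rank_normal_transform(filled, factor_id=fid)
        except ValueError as err:
            raise ValueError(f"normalization failed for factor {fid!r}: {err}") from err
    return out
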