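"""Storey-style q-values shared by the pair and triplet screening stages.

The q-value of a test is the smallest false discovery rate at which it would
be declared significant.  We use the plug-in estimator of the null proportion

    pi0 = #{p_i > lambda} / ((1 - lambda) * m),

capped into [1/m, 1], at a single lambda (default 0.5) rather than the
spline smoother: the permutation p-values produced by this package live on a
discrete lattice k/(N+1), where the smoother is unreliable.  With pi0 = 1
the q-values reduce exactly to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PvalueFamily:
    """A family of p-values with the estimated pi0 and derived q-values."""

    p: np.ndarray
    pi0: float
    q: np.ndarray


def estimate_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Single-lambda plug-in estimate of the proportion of true nulls."""
    p = np.asarray(p, dtype=float)
    m = p.size
    pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def storey_qvalues(p, lam: float = 0.5, pi0: float | str = "storey") -> PvalueFamily:
    """q-values via the step-up construction q_(i) = min_{j>=i} pi0*m*p_(j)/j.

    ``pi0`` may be "storey" (plug-in estimate at lambda=``lam``), "one"
    (forces Benjamini-Hochberg behaviour) or an explicit float.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 == "storey":
        pi0_val = estimate_pi0(p, lam)
    elif pi0 == "one":
        pi0_val = 1.0
    else:
        pi0_val = float(pi0)
        if not 0 < pi0_val <= 1:
            raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="stable")
    q_sorted = pi0_val * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return PvalueFamily(p=p, pi0=pi0_val, q=q)
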