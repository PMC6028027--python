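"""Shared statistical primitives: BH-FDR and the beta-binomial likelihood.

The beta-binomial is parameterized by mean ``mu`` and precision ``s``
(shape parameters ``a = mu*s``, ``b = (1-mu)*s``); overdispersion
``phi = 1/s`` is bounded below at 1e-6 for numerical stability, at which
point the distribution is indistinguishable from a binomial.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["bh_fdr", "betabinom_loglik", "MAX_PRECISION"]

MAX_PRECISION = 1e6  # s = 1/phi; phi >= 1e-6


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics,
    clipped to 1; ties and arbitrary input order are handled exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def betabinom_loglik(k: np.ndarray, n: np.ndarray, mu: float, s: float) -> float:
    """Sum of beta-binomial log-pmfs over replicates.

    Written out with gammaln (rather than scipy.stats.betabinom.logpmf)
    because it sits inside per-event optimizer loops; the two agree to
    floating-point precision.
    """
    a = mu * s
    b = (1.0 - mu) * s
    ll = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )
    return float(np.sum(ll))
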