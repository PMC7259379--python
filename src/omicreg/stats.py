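"""Small shared statistical primitives (FDR adjustment, KS wrapper)."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped to 1.  Preserves the
    ordering of the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def ks_two_sample(a, b, method: str = "asymp") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test; returns (D, p)."""
    res = sps.ks_2samp(np.asarray(a, float), np.asarray(b, float), method=method)
    return float(res.statistic), float(res.pvalue)
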