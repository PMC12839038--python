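"""Shared statistical helpers used across pipeline stages."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns q-values: q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1,
    in the input order.  NaN entries propagate as NaN and do not count
    toward m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[finite] = out
    return q
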