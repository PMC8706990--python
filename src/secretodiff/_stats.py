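"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
import pandas as pd


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing values (NaN) are propagated: they do not count toward the number
    of tests and come back as NaN.  Raises ``ValueError`` for p-values
    outside [0, 1].
    """
    p = np.asarray(pd.to_numeric(pd.Series(p_values), errors="coerce"), dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[valid] = adj
    return q
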