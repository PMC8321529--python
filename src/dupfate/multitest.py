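"""Multiple-testing helpers shared across modules."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= i} ( p_(j) * m / j ) for the sorted p-values, mapped back
    to input order; NaNs propagate and do not count toward m.

    Parameters
    ----------
    pvalues : array-like of float
        Raw p-values in (0, 1]; NaN allowed for untestable entries.

    Returns
    -------
    numpy.ndarray
        Adjusted values, same shape as input, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")  # ties broken by input order
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q
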