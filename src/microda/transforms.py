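"""Shared normalizations, the CLR transform, and BH multiple-testing correction."""

from __future__ import annotations

import numpy as np

from .tables import CountTable

__all__ = ["tss_normalize", "clr_transform", "benjamini_hochberg"]


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, CountTable):
        return table.counts.astype(np.float64)
    return np.asarray(table, dtype=np.float64)


def tss_normalize(table) -> np.ndarray:
    """Total-sum scaling: divide each sample (column) by its library size."""
    counts = _as_matrix(table)
    depths = counts.sum(axis=0)
    if np.any(depths <= 0):
        bad = int(np.flatnonzero(depths <= 0)[0])
        name = table.sample_ids[bad] if isinstance(table, CountTable) else str(bad)
        raise ValueError(f"sample {name!r} has zero total count")
    return counts / depths


def clr_transform(table, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform with a pseudocount.

    clr(i, s) = ln((c_is + pc) / g_s) with g_s the geometric mean of the
    pseudocounted column; each output column sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logc = np.log(_as_matrix(table) + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are allowed; they are excluded from the number of tests m and
    returned as NaN in place.
    """
    p = np.asarray(p, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out
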