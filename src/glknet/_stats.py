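"""Shared statistical helpers: vectorized Welch t-tests and BH adjustment.

The Welch test is implemented on top of scipy's t distribution rather than
``scipy.stats.ttest_ind`` because the pipeline needs explicit conventions for
degenerate inputs: a variance floor for perfectly separated groups and a
(t=0, p=1) convention when both groups are constant with equal means.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GlknetError

#: variance floor used when a group is constant but means differ
VAR_FLOOR = 1e-12


def welch_ttest(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Two-sided Welch (unequal-variance) t-test along ``axis``.

    Returns ``(t, p, df, mean_a, mean_b)`` as arrays. Groups must have >=2
    observations. Zero variance in both groups with equal means yields
    (t=0, p=1); with unequal means the variance floor produces a p-value
    indistinguishable from 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = a.shape[axis]
    nb = b.shape[axis]
    if na < 2 or nb < 2:
        raise GlknetError(f"Welch t-test needs >=2 observations per group (got {na} and {nb})")
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    degenerate = (va < VAR_FLOOR) & (vb < VAR_FLOOR)
    va = np.maximum(va, VAR_FLOOR)
    vb = np.maximum(vb, VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # both groups constant and equal: no evidence either way
    null_mask = degenerate & np.isclose(ma, mb)
    t = np.where(null_mask, 0.0, t)
    p = np.where(null_mask, 1.0, p)
    return t, p, df, ma, mb


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise GlknetError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
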