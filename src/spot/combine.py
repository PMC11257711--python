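"""Aggregation of per-radius p-values into one omnibus p-value.

The Cauchy combination test maps each p-value to a standard-Cauchy quantile,
T = sum_p w_p * tan(pi * (0.5 - p_p)), and refers T back to the standard
Cauchy upper tail.  Because the Cauchy tail is essentially unchanged under
arbitrary dependence among the components, the per-radius p-values — which
are highly correlated across neighboring radii — need no dependence
adjustment.  Naive min-p / max-p comparators and Benjamini-Hochberg FDR
adjustment across multiple cell-type tests are provided alongside.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["cauchy_combine", "naive_extreme_pvalue", "bh_fdr"]

_P_FLOOR = 1e-15


def cauchy_combine(pvalues, weights=None) -> tuple[float, float]:
    """Cauchy combination of (possibly dependent) p-values.

    Undefined entries (NaN) are dropped and the weights renormalized over
    the remaining ones.  Very small p-values use the series form of the
    tangent, tan(pi*(0.5 - p)) ~ 1/(pi*p), to avoid overflow; p-values are
    clipped just below 1.

    Returns ``(T, omnibus_pvalue)``.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != p.shape:
            raise ValueError("weights must match pvalues in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    defined = ~np.isnan(p)
    p, w = p[defined], w[defined]
    if p.size == 0:
        raise ValueError("no defined p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()
    p = np.minimum(p, 1.0 - _P_FLOOR)
    terms = np.where(
        p < _P_FLOOR,
        1.0 / (np.pi * np.maximum(p, np.finfo(float).tiny)),
        np.tan(np.pi * (0.5 - p)),
    )
    T = float(np.sum(w * terms))
    if T > 1e15:
        omnibus = 1.0 / (np.pi * T)  # upper-tail series, avoids arctan underflow
    else:
        omnibus = 0.5 - np.arctan(T) / np.pi
    omnibus = float(np.clip(omnibus, np.finfo(float).tiny, 1.0 - _P_FLOOR))
    return T, omnibus


def naive_extreme_pvalue(pvalues, which: str = "best") -> tuple[int, float]:
    """Minimum ("best") or maximum ("worst") p-value over the radius grid.

    These are the naive single-radius procedures: cherry-picking the most
    significant radius inflates the type-I error severely, while the least
    significant one is nearly powerless.  Ties break to the smallest radius
    index.  Returns ``(radius_index, pvalue)`` on the original index scale.
    """
    if which not in ("best", "worst"):
        raise ValueError(f"which must be 'best' or 'worst', got {which!r}")
    p = np.asarray(pvalues, dtype=float).ravel()
    defined = np.flatnonzero(~np.isnan(p))
    if defined.size == 0:
        raise ValueError("no defined p-values")
    vals = p[defined]
    k = int(np.argmin(vals)) if which == "best" else int(np.argmax(vals))
    idx = int(defined[k])
    return idx, float(p[idx])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
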