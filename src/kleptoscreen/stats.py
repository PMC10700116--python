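"""Shared statistical helpers.

A single Benjamini–Hochberg routine is used everywhere in the package so that
expression and enrichment FDRs are guaranteed to come from the same procedure.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray
        Monotone, capped-at-1 adjusted values in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
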