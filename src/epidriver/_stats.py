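"""Small shared statistical helpers (multiple-testing wrappers)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def bonferroni(pvalues, n_tests=None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    n = len(p) if n_tests is None else n_tests
    return np.minimum(p * n, 1.0)
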