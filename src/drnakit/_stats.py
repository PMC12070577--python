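"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        out = np.full(p.shape, np.nan)
        mask = ~np.isnan(p)
        if mask.any():
            out[mask] = multipletests(p[mask], method="fdr_bh")[1]
        return out
    return multipletests(p, method="fdr_bh")[1]
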