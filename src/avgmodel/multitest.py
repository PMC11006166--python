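"""Multiple-testing adjustments used by the fitting and screening code.

Holm's step-down correction controls the family-wise error rate over all
non-intercept terms of a single fit; the Benjamini-Hochberg step-up procedure
controls the FDR over the per-gene background contrasts of a screen.  Both
wrap the standard statsmodels routines and return order-preserving adjusted
p-values capped at 1.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_adjust", "bh_adjust"]


def _adjust(p, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values (FWER control)."""
    return _adjust(p, "holm")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    return _adjust(p, "fdr_bh")
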