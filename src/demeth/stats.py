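"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (q-values).

    NaN entries (untested hypotheses) are passed through as NaN and do not
    count toward the number of tests.  Always satisfies q >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
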