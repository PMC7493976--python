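"""Small shared statistical tests: two-tailed Fisher exact p and BH-FDR.

The two-tailed Fisher p-value is the sum of hypergeometric probabilities of
all 2x2 tables with the observed margins that are no more probable than the
observed table.  It is computed here directly from the hypergeometric pmf
(with a 1e-7 relative tolerance when comparing tie probabilities, so exact
ties are not lost to floating point), which keeps batch sweeps over many
tables cheap.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_TIE_REL_TOL = 1e-7


def hypergeom_support_pmf(n: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of cell a for fixed margins (total n, row1, col1)."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    return support, pmf


def two_tailed_p_from_pmf(pmf: np.ndarray, idx: int) -> float:
    """Two-tailed p for support point ``idx`` given the margin pmf."""
    p_obs = pmf[idx]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(p, 1.0)


def fisher_two_tailed(table) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on a 2x2 table -> (odds ratio, p).

    The odds ratio is the sample odds ratio; when a margin is zero there is
    no contrast and it is 1 by convention, and a single zero cell gets the
    Haldane 0.5 correction (both logged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be integer counts")
    a, b, c, d = (int(x) for x in np.round(t).ravel())
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, n - row1, col1, n - col1) == 0:
        logger.info("degenerate margin in 2x2 table; odds ratio 1 by convention")
        return 1.0, 1.0
    support, pmf = hypergeom_support_pmf(n, row1, col1)
    p = two_tailed_p_from_pmf(pmf, a - int(support[0]))
    if b * c == 0 or a * d == 0:
        logger.info("zero cell in 2x2 table; Haldane 0.5 correction for odds ratio")
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
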