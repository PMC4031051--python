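"""Closed-form 2x2 Pearson chi-square shared by QC, tree and association tests.

The statistic for table [[a, b], [c, d]] is n(ad - bc)^2 / (r1 r2 c1 c2)
with no continuity correction; it is defined as 0 whenever any margin is
zero (degenerate table), which keeps downstream filters NaN-free.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def chi2_2x2(a, b, c, d):
    """Vectorised Pearson chi-square (1 df) for 2x2 tables.

    Parameters are the four cells, scalars or broadcastable arrays:
    rows are the two groups, columns the two outcomes. Returns an array
    (or scalar) of the same broadcast shape.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


def chi2_2x2_p(a, b, c, d):
    """Chi-square statistic and asymptotic p-value (1 df) for 2x2 tables."""
    stat = chi2_2x2(a, b, c, d)
    return stat, stats.chi2.sf(stat, df=1)
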