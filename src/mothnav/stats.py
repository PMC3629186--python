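"""Statistical tests used by the experiment drivers.

Thin wrappers over scipy.stats with the conventions fixed in one place
(two-sided by default, mid-rank tie handling), plus the Rayleigh test of
circular non-uniformity (Zar's approximation of the p-value, accurate for
n >= 10, which is also the smallest sample the track-angle analysis
accepts).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "kruskal_wallis", "fisher_exact", "rayleigh"]


def mann_whitney(a, b, alternative: str = "two-sided"):
    """Mann-Whitney U test; returns (U, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups):
    """Kruskal-Wallis H test over >= 2 groups; returns (H, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table, alternative: str = "two-sided"):
    """Fisher exact test on a 2x2 table; returns the p-value."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    return float(sps.fisher_exact(table, alternative=alternative)[1])


def rayleigh(angles_rad):
    """Rayleigh test of non-uniformity for circular data; returns (z, p).

    z = n * R^2 with R the mean resultant length; p follows Zar's
    large-sample correction.  All-equal angles give R = 1 and a minimal p.
    """
    a = np.asarray(angles_rad, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need at least two angles")
    r = math.hypot(np.cos(a).sum(), np.sin(a).sum()) / n
    z = n * r * r
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (n * r) ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, 0.0), 1.0))
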