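"""Group comparison and probability-space distances.

Gamma parameters and moments extracted per participant are compared across
groups with the nonparametric Kruskal-Wallis test (rank-based chi-square
statistic with tie correction).  Distributions of micro-movement spike
amplitudes are compared with the 1-D Wasserstein / Earth-mover's distance,
which for one-dimensional samples equals the integral of the absolute CDF
difference.  Pairwise matrices carry significance marks at the 0.01 (star)
and 0.05 (circle) levels; raw p-values are reported by default, with an
optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import wasserstein_distance

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "kruskal_wallis",
    "emd_1d",
    "pairwise_emd",
    "pairwise_significance",
    "significance_marks",
]


def _as_groups(groups):
    if isinstance(groups, dict):
        items = [(k, np.asarray(v, dtype=float)) for k, v in groups.items()]
    else:
        items = [(i, np.asarray(v, dtype=float)) for i, v in enumerate(groups)]
    for k, v in items:
        if v.size == 0:
            raise InvalidInputError(f"group {k!r} is empty")
    return items


def kruskal_wallis(groups):
    """Kruskal-Wallis H test across two or more groups.

    Returns ``(h_statistic, p_value)``.  The H statistic is the rank-based
    replacement of the one-way ANOVA F, corrected for ties; the p-value comes
    from the chi-square distribution with k-1 degrees of freedom.  When every
    pooled observation is identical all ranks are tied, H is 0 and p is 1.
    """
    items = _as_groups(groups)
    if len(items) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = [v for _, v in items]
    if sum(v.size for v in arrays) < 5:
        raise InsufficientDataError("need at least 5 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def emd_1d(u, v) -> float:
    """1-D Earth-mover's distance between two empirical samples."""
    return float(wasserstein_distance(np.asarray(u, float), np.asarray(v, float)))


def pairwise_emd(samples: dict, min_n: int = 5) -> pd.DataFrame:
    """Symmetric matrix of pairwise 1-D EMD values with a zero diagonal.

    ``samples`` maps label (e.g. emotion) -> amplitude sample.  Cells
    involving a sample with fewer than ``min_n`` observations are NaN.
    """
    if len(samples) < 2:
        raise InvalidInputError("need at least 2 labelled samples")
    names = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if arrays[a].size < min_n or arrays[b].size < min_n:
                d = np.nan
            else:
                d = emd_1d(arrays[a], arrays[b])
            mat.loc[a, b] = d
            mat.loc[b, a] = d
    return mat


def pairwise_significance(
    samples: dict,
    correction: str = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Pairwise two-group Kruskal-Wallis p-values; diagonal is 1 by convention.

    ``correction='bh'`` applies the Benjamini-Hochberg adjustment across the
    k(k-1)/2 unique comparisons; by default raw p-values are reported, as is
    customary when threshold marks rather than adjusted error rates are shown.
    """
    if len(samples) < 2:
        raise InvalidInputError("need at least 2 labelled samples")
    if correction not in (None, "bh"):
        raise InvalidInputError("correction must be None or 'bh'")
    names = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    pvals = []
    for a, b in pairs:
        if arrays[a].size < min_n or arrays[b].size < min_n:
            pvals.append(np.nan)
        else:
            pvals.append(kruskal_wallis({a: arrays[a], b: arrays[b]})[1])
    if correction == "bh":
        finite = ~np.isnan(pvals)
        adj = np.asarray(pvals, dtype=float)
        if finite.any():
            adj[finite] = stats.false_discovery_control(adj[finite])
        pvals = adj.tolist()
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for (a, b), p in zip(pairs, pvals):
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def significance_marks(
    pvalues: pd.DataFrame,
    star_level: float = 0.01,
    circle_level: float = 0.05,
) -> pd.DataFrame:
    """Threshold marks for a p-value matrix: 'star' (<0.01), 'circle' (<0.05).

    Every star cell would also qualify as a circle; the stronger mark wins.
    The diagonal is left unmarked.
    """
    marks = pd.DataFrame("", index=pvalues.index, columns=pvalues.columns)
    for a in pvalues.index:
        for b in pvalues.columns:
            if a == b:
                continue
            p = pvalues.loc[a, b]
            if np.isnan(p):
                continue
            if p < star_level:
                marks.loc[a, b] = "star"
            elif p < circle_level:
                marks.loc[a, b] = "circle"
    return marks
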