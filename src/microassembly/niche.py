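"""Levins niche breadth and overlap on a community matrix.

Samples play the role of resource states: each taxon's counts are normalized
across samples to a habitat-use distribution p_ij, so breadth is the inverse
Simpson concentration B_i = 1 / sum_j p_ij^2, ranging from 1 (a single
sample) to n_samples (uniform occupancy).  The Levins overlap O_ik =
sum_j p_ij p_kj / sum_j p_ij^2 projects taxon k's use onto taxon i's and is
deliberately asymmetric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import CommunityMatrix

__all__ = [
    "levins_breadth",
    "community_breadth",
    "levins_overlap",
    "overlap_degree",
    "default_overlap_threshold",
]

#: minimum occupancy (samples with count > 0) for a taxon to enter Bcom
DEFAULT_OCCUPANCY_MIN = 5

#: percentile of off-diagonal overlaps used as the overlap-network threshold
DEFAULT_OVERLAP_PERCENTILE = 90.0


def _use_distribution(matrix: CommunityMatrix) -> pd.DataFrame:
    """Taxon habitat-use distributions p_ij (taxa x samples), dropping empties."""
    counts = matrix.counts.T.astype(float)  # taxa x samples
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index
    if len(empty):
        warnings.warn(
            f"excluding {len(empty)} all-zero taxa from niche calculations",
            stacklevel=3,
        )
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    return counts.div(totals, axis=0)


def levins_breadth(matrix: CommunityMatrix) -> pd.Series:
    """Levins niche breadth B_i = 1 / sum_j p_ij^2 per taxon."""
    p = _use_distribution(matrix)
    return 1.0 / (p**2).sum(axis=1)


def community_breadth(
    matrix: CommunityMatrix, occupancy_min: int = DEFAULT_OCCUPANCY_MIN
) -> float:
    """Community-level breadth Bcom: mean B_i over taxa occupying
    at least ``occupancy_min`` samples."""
    b = levins_breadth(matrix)
    occupancy = (matrix.counts > 0).sum(axis=0).reindex(b.index)
    kept = b[occupancy >= occupancy_min]
    if kept.empty:
        raise ValueError(f"no taxon occupies >= {occupancy_min} samples")
    return float(kept.mean())


def levins_overlap(matrix: CommunityMatrix) -> pd.DataFrame:
    """Asymmetric Levins overlap O_ik = sum_j p_ij p_kj / sum_j p_ij^2."""
    p = _use_distribution(matrix)
    v = p.to_numpy()
    cross = v @ v.T                     # sum_j p_ij p_kj
    conc = (v**2).sum(axis=1)           # sum_j p_ij^2
    o = cross / conc[:, None]
    return pd.DataFrame(o, index=p.index, columns=p.index)


def default_overlap_threshold(overlap: pd.DataFrame,
                              percentile: float = DEFAULT_OVERLAP_PERCENTILE) -> float:
    """Percentile of the off-diagonal overlap values (units-free default)."""
    v = overlap.to_numpy(float).copy()
    np.fill_diagonal(v, np.nan)
    return float(np.nanpercentile(v, percentile))


def overlap_degree(overlap: pd.DataFrame, threshold: float) -> float:
    """Mean degree of the overlap network.

    Edge (i, k) exists iff max(O_ik, O_ki) >= threshold, i != k; returns
    2|E| / |V|.
    """
    v = overlap.to_numpy(float)
    if not (0 < threshold <= np.nanmax(v)):
        raise ValueError(
            f"threshold {threshold} outside (0, max overlap {np.nanmax(v):g}]"
        )
    sym = np.maximum(v, v.T)
    np.fill_diagonal(sym, -np.inf)
    n_edges = int((np.triu(sym >= threshold, k=1)).sum())
    return 2.0 * n_edges / v.shape[0]
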