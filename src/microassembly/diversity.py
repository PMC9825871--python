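"""Alpha/beta diversity, ordination, PERMANOVA, and distance-decay regression.

Shannon entropy is in nats so that Pielou's evenness J = H / ln(S) is
scale-consistent.  Bray-Curtis is computed on row-normalized relative
abundances by default.  PCoA delegates to scikit-bio (Gower double-centering
with negative-eigenvalue reporting).  PERMANOVA is a seeded, one-factor
implementation whose p-values are reproducible bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, mannwhitneyu
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix as _SkbioDM

from .matrix import CommunityMatrix

__all__ = [
    "shannon",
    "pielou",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
    "group_compare",
    "haversine_km",
    "distance_decay",
    "DecayFit",
]

EARTH_RADIUS_KM = 6371.0088


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p (nats) of one count vector."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Pielou's evenness J = H / ln(S), S = observed richness."""
    x = np.asarray(counts, dtype=float)
    s = int((x > 0).sum())
    if s < 2:
        raise ValueError(f"Pielou evenness undefined for richness {s} < 2")
    return shannon(x) / np.log(s)


def alpha_diversity(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-sample richness, Shannon H, and Pielou J."""
    rows = {}
    for sid, row in matrix.counts.iterrows():
        x = row.to_numpy(float)
        s = int((x > 0).sum())
        h = shannon(x)
        rows[sid] = {
            "richness": s,
            "shannon": h,
            "pielou": h / np.log(s) if s >= 2 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(matrix: CommunityMatrix, transform: str = "relative") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix (samples x samples).

    BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / sum_i (x_i + y_i), computed on
    relative abundances (default) or raw counts.
    """
    if transform not in ("relative", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    v = matrix.values().astype(float)
    if transform == "relative":
        totals = v.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero-sum sample under transform='relative'")
        v = v / totals[:, None]
    d = squareform(pdist(v, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.counts.index, columns=matrix.counts.index)


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame           # samples x retained axes
    eigenvalues: np.ndarray             # full spectrum, descending (may be < 0)
    proportion_explained: np.ndarray    # per retained axis, of positive-eigenvalue sum


def pcoa(distance: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Axes with non-positive eigenvalues are dropped; if fewer than ``n_axes``
    remain the result is truncated with a warning.
    """
    import warnings

    dm = _SkbioDM(distance.to_numpy(float), ids=[str(i) for i in distance.index])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    n_pos = int((eig > 1e-10).sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    if n_axes == 0:
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = distance.index
    coords.columns = [f"PCo{i + 1}" for i in range(n_axes)]
    prop = res.proportion_explained.to_numpy()[:n_axes]
    return OrdinationResult(coords, eig, prop)


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int

    def __str__(self) -> str:
        return (
            f"PERMANOVA: pseudo-F = {self.pseudo_F:.4f}, R2 = {self.R2:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations)"
        )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Total and within-group sums of squared distances."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total, ss_within


def permanova(
    distance: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (one factor).

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) from the squared
    distance partition; p is the permutation tail probability
    (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under seeded label
    shuffling.
    """
    labels = np.asarray(pd.Series(list(groups)).values)
    d = distance.to_numpy(float)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("groups length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = d**2
    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        _, ssw = _permanova_ss(d2, perm, a)
        ssb = ss_total - ssw
        f_perm = (ssb / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)


def group_compare(values, labels, test: str = "wilcoxon_rank_sum") -> float:
    """Two-sided two-group comparison; returns the p-value.

    Wilcoxon rank-sum with midranks: exact enumeration of the permutation
    distribution when the number of arrangements is small (<= 2e5), else the
    normal approximation with tie correction.
    """
    if test != "wilcoxon_rank_sum":
        raise ValueError(f"unknown test {test!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 values")
    from math import comb

    if comb(len(x) + len(y), len(x)) <= 200_000:
        return _exact_ranksum_p(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    return float(res.pvalue)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating group-1 index sets."""
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks handle ties
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - expected) - 1e-12
    total = hits = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - expected) >= dev_obs:
            hits += 1
    return hits / total


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distances(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (km) from latitude/longitude columns."""
    ids = list(meta.index)
    lat = meta["latitude"].to_numpy(float)
    lon = meta["longitude"].to_numpy(float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class DecayFit:
    """OLS fit of community similarity (1 - Bray-Curtis) on geographic distance.

    The slope is similarity per km (negative under distance decay).  The
    F-test p-value treats pairs as independent, which they are not; it is
    anti-conservative and flagged as such.
    """

    slope: float
    intercept: float
    R2: float
    p_value: float
    n_pairs: int
    caveat: str = "pairs are non-independent; p-value is anti-conservative"


def distance_decay(distance: pd.DataFrame, meta: pd.DataFrame) -> DecayFit:
    """Regress similarity on great-circle distance over all unordered pairs."""
    shared = [s for s in distance.index if s in meta.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples with coordinates")
    d = distance.loc[shared, shared].to_numpy(float)
    geo = geographic_distances(meta.loc[shared]).to_numpy(float)
    iu = np.triu_indices(len(shared), k=1)
    sim = 1.0 - d[iu]
    km = geo[iu]
    if np.ptp(km) == 0:
        raise ValueError("all samples are co-located: zero variance in distance")
    fit = linregress(km, sim)
    return DecayFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        R2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_pairs=len(km),
    )
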