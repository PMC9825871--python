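"""Community-assembly inference: Sloan neutral model and stochasticity ratio.

Two complementary lines of evidence:

* :class:`SloanNCM` fits Sloan's neutral community model, which predicts a
  taxon's occurrence frequency across samples from its mean relative
  abundance p via the beta distribution ``Beta(Nm*p, Nm*(1-p))`` truncated at
  a detection limit — one free parameter, the dispersal level Nm.  A high R²
  means occurrence frequencies look neutral (dispersal + drift); a low R²
  means selection decouples occupancy from abundance.
* :func:`nst` computes the normalized stochasticity ratio: the observed
  pairwise dissimilarity of each within-group sample pair is compared with
  its expectation under a null model that preserves per-sample richness and
  draws occupancy proportional to occurrence frequency.  NST of 100% means
  observed dissimilarity is exactly the null expectation (pure stochasticity);
  0% means extreme determinism, with 50% as the conventional boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.stats import beta as beta_dist

from .matrix import CommunityMatrix

__all__ = [
    "SloanNCM",
    "NCMResults",
    "fit_ncm",
    "null_randomize",
    "nst",
    "NSTResult",
]

NM_BOUNDS = (1e-3, 1e7)  # search bounds for Nm (log-scale optimization)


def sloan_occurrence_frequency(p, Nm: float, detection_limit: float):
    """Predicted occurrence frequency 1 - BetaCDF(d; Nm*p, Nm*(1-p)).

    Monotone non-decreasing in p at fixed Nm: more abundant taxa are seen
    above the detection limit in more samples.
    """
    p = np.asarray(p, dtype=float)
    a = np.clip(Nm * p, 1e-12, None)
    b = np.clip(Nm * (1.0 - p), 1e-12, None)
    return beta_dist.sf(detection_limit, a, b)


class SloanNCM:
    """Sloan neutral community model for a community matrix.

    Parameters
    ----------
    matrix
        Validated community matrix (>= 10 samples, >= 20 taxa).
    detection_limit
        Relative-abundance detection threshold d.  ``"auto"`` uses
        d = ln(2)/N (N = mean sample depth): under binomial read sampling a
        taxon at latent abundance x is seen with probability
        1 - (1-x)^N ~ 1 - exp(-N x), and ln(2)/N is the abundance at which
        that probability crosses 1/2, so the hard threshold is centred on
        the smooth detection curve.  The one-read rule d = 1/N is available
        as ``detection_limit=1/N`` but overestimates Nm on count data
        because it ignores mass detected below one expected read.
    """

    def __init__(self, matrix: CommunityMatrix, detection_limit="auto"):
        if matrix.n_samples < 10:
            raise ValueError(f"NCM needs >= 10 samples, got {matrix.n_samples}")
        if matrix.n_taxa < 20:
            raise ValueError(f"NCM needs >= 20 taxa, got {matrix.n_taxa}")
        counts = matrix.values().astype(float)
        self.N = float(counts.sum(axis=1).mean())
        self.detection_limit = (
            np.log(2.0) / self.N if detection_limit == "auto" else float(detection_limit)
        )
        rel = counts / counts.sum(axis=1, keepdims=True)
        self.p = rel.mean(axis=0)
        self.f = (counts > 0).mean(axis=0)
        self.n_samples = matrix.n_samples
        self.taxon_ids = matrix.taxon_ids
        # taxa absent everywhere carry no occurrence information
        keep = self.p > 0
        self.p, self.f = self.p[keep], self.f[keep]
        self.taxon_ids = [t for t, k in zip(self.taxon_ids, keep) if k]

    def _sse(self, log10_nm: float) -> float:
        pred = sloan_occurrence_frequency(self.p, 10.0**log10_nm, self.detection_limit)
        return float(((self.f - pred) ** 2).sum())

    def fit(self) -> "NCMResults":
        """Estimate Nm by bounded least squares on occurrence frequencies."""
        lo, hi = np.log10(NM_BOUNDS)
        opt = minimize_scalar(self._sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        log_nm = float(opt.x)
        at_bound = log_nm - lo < 1e-6 or hi - log_nm < 1e-6
        if at_bound:
            warnings.warn("Nm estimate at optimization bound", stacklevel=2)
        nm = 10.0**log_nm
        pred = sloan_occurrence_frequency(self.p, nm, self.detection_limit)
        ss_res = float(((self.f - pred) ** 2).sum())
        ss_tot = float(((self.f - self.f.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

        ci_low, ci_high = _wilson_interval(pred, self.n_samples)
        table = pd.DataFrame(
            {
                "mean_rel_abundance": self.p,
                "observed_freq": self.f,
                "predicted_freq": pred,
                "ci_low": ci_low,
                "ci_high": ci_high,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )
        above = float((self.f > ci_high).mean())
        below = float((self.f < ci_low).mean())
        return NCMResults(
            model=self,
            Nm=nm,
            m=nm / self.N,
            N=self.N,
            R2=r2,
            taxa=table,
            frac_above=above,
            frac_below=below,
            frac_within=1.0 - above - below,
            at_bound=at_bound,
        )


def _wilson_interval(p_hat: np.ndarray, n: int, z: float = 1.959963984540054):
    """95% Wilson score interval for a binomial proportion."""
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


@dataclass
class NCMResults:
    """Fitted Sloan neutral model: estimates, fit quality, per-taxon envelope."""

    model: SloanNCM
    Nm: float
    m: float
    N: float
    R2: float
    taxa: pd.DataFrame
    frac_above: float
    frac_below: float
    frac_within: float
    at_bound: bool = False

    def summary(self) -> str:
        lines = [
            "Sloan neutral community model",
            "=" * 45,
            f"samples                 {self.model.n_samples:>10d}",
            f"taxa fitted             {len(self.taxa):>10d}",
            f"mean depth N            {self.N:>10.1f}",
            f"detection limit d       {self.model.detection_limit:>10.3g}",
            f"Nm (dispersal level)    {self.Nm:>10.2f}",
            f"m  (migration rate)     {self.m:>10.5f}",
            f"R2                      {self.R2:>10.4f}",
            f"taxa above 95% CI       {self.frac_above:>10.1%}",
            f"taxa within 95% CI      {self.frac_within:>10.1%}",
            f"taxa below 95% CI       {self.frac_below:>10.1%}",
        ]
        if self.at_bound:
            lines.append("warning: Nm at optimization bound")
        return "\n".join(lines)

    def predict(self, p) -> np.ndarray:
        """Occurrence frequency predicted at abundance(s) p."""
        return sloan_occurrence_frequency(p, self.Nm, self.model.detection_limit)


def fit_ncm(matrix: CommunityMatrix, detection_limit="auto") -> NCMResults:
    """Convenience wrapper: ``SloanNCM(matrix, detection_limit).fit()``."""
    return SloanNCM(matrix, detection_limit).fit()


# ---------------------------------------------------------------------------
# Normalized stochasticity ratio
# ---------------------------------------------------------------------------

def null_randomize(matrix: CommunityMatrix, algorithm: str = "PF",
                   seed=0) -> CommunityMatrix:
    """One null community under the PF algorithm.

    Each null sample keeps its observed richness; its taxa are drawn without
    replacement with probability proportional to observed occurrence
    frequency across samples, and the sample's observed non-zero counts are
    reassigned to the drawn taxa uniformly at random.
    """
    if algorithm != "PF":
        raise ValueError(f"unknown null algorithm {algorithm!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = matrix.values()
    occ = (counts > 0).sum(axis=0).astype(float)
    occupied = np.flatnonzero(occ > 0)
    weights = occ[occupied] / occ[occupied].sum()
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        nonzero = row[row > 0]
        taxa = rng.choice(occupied, size=len(nonzero), replace=False, p=weights)
        out[i, taxa] = rng.permutation(nonzero)
    return CommunityMatrix(
        pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    )


def _pairwise(counts: np.ndarray, metric: str) -> np.ndarray:
    """Condensed pairwise dissimilarity for NST (relative BC or binary Jaccard)."""
    if metric == "bray_curtis":
        v = counts.astype(float)
        v = v / v.sum(axis=1, keepdims=True)
        return pdist(v, metric="braycurtis")
    if metric == "jaccard":
        return pdist(counts > 0, metric="jaccard")
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class NSTResult:
    """Normalized stochasticity ratio per group."""

    pairs: pd.DataFrame          # sample_i, sample_j, group, D_obs, D_null_mean, ESS, NST_pair
    group_nst: dict              # group -> NST in percent
    null_config: dict = field(default_factory=dict)

    def classification(self) -> dict:
        """'stochastic-dominated' iff group NST > 50%."""
        return {
            g: ("stochastic-dominated" if v > 50.0 else "deterministic-dominated")
            for g, v in self.group_nst.items()
        }


def nst(
    matrix: CommunityMatrix,
    groups,
    metric: str = "jaccard",
    n_null: int = 1000,
    algorithm: str = "PF",
    seed: int = 0,
) -> NSTResult:
    """Normalized stochasticity ratio per group of samples.

    For each within-group pair: selection strength
    ``ESS = (Dbar - D_obs)/Dbar`` if ``D_obs <= Dbar`` else
    ``(D_obs - Dbar)/(1 - Dbar)``, and ``NST_pair = 1 - ESS``; the group NST
    is the mean NST_pair in percent.  The null expectation ``Dbar`` is the
    mean dissimilarity over ``n_null`` seeded randomizations of the group's
    submatrix.
    """
    labels = pd.Series(list(groups), index=matrix.counts.index)
    rng = np.random.default_rng(seed)
    rows = []
    group_means = {}
    for g in pd.unique(labels):
        ids = labels.index[labels == g]
        if len(ids) < 4:
            raise ValueError(f"group {g!r} has {len(ids)} samples; need >= 4")
        sub = matrix.select_samples(ids).drop_empty_taxa()
        counts = sub.values()
        d_obs = _pairwise(counts, metric)
        d_null = np.zeros_like(d_obs)
        for _ in range(n_null):
            null = null_randomize(sub, algorithm=algorithm, seed=rng)
            d_null += _pairwise(null.values(), metric)
        d_null /= n_null

        pair_idx = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        nst_vals = []
        for k, (i, j) in enumerate(pair_idx):
            dbar, dobs = d_null[k], d_obs[k]
            if dbar <= 0 or dbar >= 1:
                warnings.warn(
                    f"pair ({ids[i]}, {ids[j]}): degenerate null mean {dbar:g}; excluded",
                    stacklevel=2,
                )
                continue
            if dobs <= dbar:
                ess = (dbar - dobs) / dbar
            else:
                ess = (dobs - dbar) / (1.0 - dbar)
            nst_pair = 1.0 - ess
            nst_vals.append(nst_pair)
            rows.append({
                "sample_i": ids[i], "sample_j": ids[j], "group": g,
                "D_obs": dobs, "D_null_mean": dbar, "ESS": ess,
                "NST_pair": nst_pair,
            })
        if not nst_vals:
            raise ValueError(f"group {g!r}: all pairs degenerate under the null")
        group_means[g] = float(np.mean(nst_vals) * 100.0)
    return NSTResult(
        pairs=pd.DataFrame(rows),
        group_nst=group_means,
        null_config={"algorithm": algorithm, "n_null": n_null,
                     "metric": metric, "seed": seed},
    )
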