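"""Synthetic community generators with known ground truth.

Three mechanisms, mirroring the processes the downstream inference stages try
to detect:

* :func:`simulate_neutral` — Sloan-type neutral assembly: each taxon's local
  relative abundance is drawn from the stationary beta marginal
  ``Beta(N*m*p_i, N*m*(1-p_i))`` around its metacommunity abundance ``p_i``,
  renormalized across taxa, then read counts are multinomial.  Ground truth is
  the migration rate ``m``.
* :func:`simulate_niche` — deterministic environmental filtering: expected
  abundance of taxon *i* in sample *s* is ``p_i * exp(-(e_s - mu_i)^2 /
  (2 sigma_i^2))`` along an environmental gradient.  Ground truth is the set
  of niche optima and widths.
* :func:`plant_network` — a latent-factor block model planting known
  positive/negative co-occurrence structure for network-recovery tests.

:func:`make_study_like` combines them into a two-region (arid/humid) field
design with region-shifted covariates: a neutral, richer "bacteria-like"
table and a gradient-filtered, poorer "fungi-like" table over the same
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .matrix import CommunityMatrix, ARID_AI_RANGE, HUMID_AI_MIN

__all__ = [
    "SyntheticTruth",
    "StudyConfig",
    "simulate_neutral",
    "simulate_niche",
    "plant_network",
    "make_study_like",
]

#: realistic post-QC amplicon sequencing depth per sample (reads)
DEFAULT_READS = 10_000

#: niche width on the unit aridity gradient that imposes strong filtering
STRONG_FILTER_SIGMA = 0.08


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic community, for recovery tests."""

    seed: int
    migration_rate: float | None = None
    metacommunity: np.ndarray | None = None
    niche_optima: np.ndarray | None = None
    niche_widths: np.ndarray | None = None
    planted_edges: list[tuple] = field(default_factory=list)
    region_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.metacommunity is not None:
            p = np.asarray(self.metacommunity, dtype=float)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("metacommunity abundances must sum to 1")
            self.metacommunity = p
        if self.niche_widths is not None:
            w = np.asarray(self.niche_widths, dtype=float)
            if (w <= 0).any():
                raise ValueError("niche widths must be positive")
            self.niche_widths = w

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        return json.dumps(d, indent=2)


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _metacommunity(n_taxa: int, kind, rng) -> np.ndarray:
    """Metacommunity relative abundances on the simplex."""
    if isinstance(kind, (list, tuple, np.ndarray)):
        p = np.asarray(kind, dtype=float)
        if len(p) != n_taxa or (p < 0).any():
            raise ValueError("given metacommunity must be non-negative, length n_taxa")
        return p / p.sum()
    if kind == "lognormal":
        # lognormal(0, 1) abundances sorted descending: canonical hollow
        # rank-abundance curve
        x = np.sort(rng.lognormal(0.0, 1.0, size=n_taxa))[::-1]
        return x / x.sum()
    if kind == "uniform":
        return np.full(n_taxa, 1.0 / n_taxa)
    raise ValueError(f"unknown metacommunity spec {kind!r}")


def _multinomial_counts(expected: np.ndarray, reads: int, rng) -> np.ndarray:
    """Draw multinomial counts per row from row-wise expected compositions."""
    probs = expected / expected.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(reads, p) for p in probs])


def _as_matrix(counts, sample_ids, taxon_ids) -> CommunityMatrix:
    return CommunityMatrix(pd.DataFrame(counts, index=sample_ids, columns=taxon_ids))


def simulate_neutral(
    n_samples: int,
    n_taxa: int,
    reads_per_sample: int = DEFAULT_READS,
    m: float = 0.1,
    metacommunity="lognormal",
    seed: int = 0,
    sample_prefix: str = "S",
    taxon_prefix: str = "OTU",
) -> tuple[CommunityMatrix, SyntheticTruth]:
    """Neutral community under Sloan stationary beta marginals.

    For each sample, each taxon's latent relative abundance is
    ``Beta(N*m*p_i, N*m*(1-p_i))`` (mean ``p_i``, concentration ``N*m``);
    the latent vector is renormalized and ``N`` reads are drawn multinomially.
    Small ``m`` means strong drift/dispersal limitation (near-monodominant
    samples); ``m`` near 1 pins every sample to the metacommunity.
    """
    if not (0 < m <= 1):
        raise ValueError(f"migration rate m must be in (0, 1], got {m}")
    if reads_per_sample < 100:
        raise ValueError("reads_per_sample must be >= 100")
    rng = np.random.default_rng(seed)
    p = _metacommunity(n_taxa, metacommunity, rng)
    conc = reads_per_sample * m
    a = np.clip(conc * p, 1e-12, None)
    b = np.clip(conc * (1.0 - p), 1e-12, None)
    latent = rng.beta(a, b, size=(n_samples, n_taxa))
    # guard against all-zero latent rows at extreme m
    latent = np.clip(latent, 1e-300, None)
    counts = _multinomial_counts(latent, reads_per_sample, rng)
    mat = _as_matrix(counts, _labels(sample_prefix, n_samples), _labels(taxon_prefix, n_taxa))
    truth = SyntheticTruth(seed=seed, migration_rate=m, metacommunity=p)
    return mat, truth


def simulate_niche(
    n_samples: int,
    n_taxa: int,
    reads_per_sample: int = DEFAULT_READS,
    env_values: Sequence[float] | None = None,
    optima: Sequence[float] | None = None,
    widths: Sequence[float] | float = STRONG_FILTER_SIGMA,
    metacommunity="lognormal",
    seed: int = 0,
    sample_prefix: str = "S",
    taxon_prefix: str = "OTU",
) -> tuple[CommunityMatrix, SyntheticTruth]:
    """Environmentally filtered community along a gradient.

    Expected abundance of taxon *i* in sample *s* is proportional to
    ``p_i * exp(-(e_s - mu_i)^2 / (2 sigma_i^2))``; counts are multinomial.
    Defaults place the gradient on [0, 1] with optima spread uniformly over
    it, so a small common width (e.g. 0.08) gives strong species sorting.
    """
    rng = np.random.default_rng(seed)
    if env_values is None:
        env = np.linspace(0.0, 1.0, n_samples)
    else:
        env = np.asarray(env_values, dtype=float)
        if len(env) != n_samples:
            raise ValueError("env_values length must equal n_samples")
    p = _metacommunity(n_taxa, metacommunity, rng)
    if optima is None:
        mu = rng.uniform(env.min(), env.max(), size=n_taxa)
    else:
        mu = np.asarray(optima, dtype=float)
    sigma = np.broadcast_to(np.asarray(widths, dtype=float), (n_taxa,)).copy()
    if (sigma <= 0).any():
        raise ValueError("all niche widths must be positive")
    # samples x taxa Gaussian niche kernel
    kernel = np.exp(-((env[:, None] - mu[None, :]) ** 2) / (2.0 * sigma[None, :] ** 2))
    expected = np.clip(p[None, :] * kernel, 1e-300, None)
    counts = _multinomial_counts(expected, reads_per_sample, rng)
    mat = _as_matrix(counts, _labels(sample_prefix, n_samples), _labels(taxon_prefix, n_taxa))
    truth = SyntheticTruth(
        seed=seed, metacommunity=p, niche_optima=mu, niche_widths=sigma
    )
    return mat, truth


def plant_network(
    n_samples: int,
    block_spec: Sequence[tuple[int, str, float]],
    n_noise_taxa: int = 0,
    reads_per_sample: int = DEFAULT_READS,
    seed: int = 0,
    taxon_prefix: str = "OTU",
) -> tuple[CommunityMatrix, SyntheticTruth]:
    """Plant block-correlated taxa for network-recovery tests.

    Each block shares a standard-normal latent factor per sample; member
    taxa load on it with loading ``+strength`` (sign "+") or alternating
    ``+/-strength`` (sign "-", so the block contains anti-correlated pairs).
    Latent Gaussians are exponentiated to log-normal abundances and read
    counts drawn multinomially.  ``planted_edges`` records every within-block
    pair with the sign of its expected correlation (the product of the two
    loading signs).
    """
    rng = np.random.default_rng(seed)
    n_block_taxa = sum(size for size, _, _ in block_spec)
    n_taxa = n_block_taxa + n_noise_taxa
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    taxa = _labels(taxon_prefix, n_taxa)

    z = np.empty((n_samples, n_taxa))
    planted: list[tuple[str, str, str]] = []
    col = 0
    for size, sign, strength in block_spec:
        if not (0 < strength <= 1):
            raise ValueError(f"latent_strength must be in (0, 1], got {strength}")
        if sign not in ("+", "-"):
            raise ValueError(f"block sign must be '+' or '-', got {sign!r}")
        factor = rng.standard_normal(n_samples)
        loadings = np.full(size, strength)
        if sign == "-":
            loadings[1::2] *= -1.0  # alternate loadings -> anti-correlated pairs
        resid = np.sqrt(1.0 - strength**2)
        for j in range(size):
            z[:, col + j] = loadings[j] * factor + resid * rng.standard_normal(n_samples)
        for a in range(size):
            for b in range(a + 1, size):
                pair_sign = "+" if loadings[a] * loadings[b] > 0 else "-"
                planted.append((taxa[col + a], taxa[col + b], pair_sign))
        col += size
    if n_noise_taxa:
        z[:, col:] = rng.standard_normal((n_samples, n_noise_taxa))

    abundances = np.exp(z)
    counts = _multinomial_counts(abundances, reads_per_sample, rng)
    mat = _as_matrix(counts, _labels("S", n_samples), taxa)
    truth = SyntheticTruth(seed=seed, planted_edges=planted)
    return mat, truth


@dataclass
class StudyConfig:
    """Design of a study-like two-region synthetic dataset.

    Defaults reproduce the field design: 26 arid + 21 humid sites, 3
    replicates each (141 samples), a latitudinal transect, and covariates
    whose means shift with region (MAP/MAT ranges follow the sampled
    climate; pH higher and carbon pools lower in the arid region).
    """

    n_arid_sites: int = 26
    n_humid_sites: int = 21
    replicates: int = 3
    reads_per_sample: int = DEFAULT_READS
    n_taxa_bacteria: int = 300
    n_taxa_fungi: int = 150
    neutral_m: float = 0.1
    niche_sigma: float = STRONG_FILTER_SIGMA
    # covariate means/sds per region: name -> ((arid_mean, arid_sd), (humid_mean, humid_sd))
    covariates: dict = field(default_factory=lambda: {
        "MAT": ((23.4, 1.5), (17.7, 2.0)),   # degC, from sampled ranges
        "MAP": ((415.0, 75.0), (1310.0, 230.0)),  # mm
        "pH": ((7.8, 0.4), (5.9, 0.6)),
        "TC": ((1.1, 0.3), (3.2, 0.9)),       # %
        "TN": ((0.10, 0.03), (0.25, 0.07)),   # %
        "DOC": ((70.0, 20.0), (160.0, 45.0)),  # mg/kg
        "DON": ((8.0, 2.5), (18.0, 5.0)),      # mg/kg
        "NO3": ((4.0, 1.5), (9.0, 3.0)),       # mg/kg
        "NH4": ((3.0, 1.0), (7.0, 2.5)),       # mg/kg
    })

    @property
    def n_samples(self) -> int:
        return (self.n_arid_sites + self.n_humid_sites) * self.replicates


def make_study_like(config: StudyConfig | None = None, seed: int = 0):
    """Generate a full two-region study: two markers, metadata, truth.

    Returns ``(bacteria_like, fungi_like, metadata, truth)``.  The
    bacteria-like table is assembled neutrally (richer, stochastic); the
    fungi-like table is filtered along the aridity-index gradient (poorer,
    deterministic) — the contrast the downstream inference should recover.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)

    records = []
    lo, hi = ARID_AI_RANGE
    sites = [("arid", i) for i in range(cfg.n_arid_sites)] + [
        ("humid", i) for i in range(cfg.n_humid_sites)
    ]
    # inland transect runs north/interior; coastal sites sit further east
    for region, i in sites:
        site_id = f"{region[:1].upper()}{i + 1:02d}"
        if region == "arid":
            ai = rng.uniform(lo + 0.01, hi - 0.01)
            lat = -19.5 - 18.0 * i / max(cfg.n_arid_sites - 1, 1)
            lon = rng.uniform(133.4, 146.0)
        else:
            ai = rng.uniform(HUMID_AI_MIN + 0.05, 1.3)
            lat = -19.5 - 18.0 * i / max(cfg.n_humid_sites - 1, 1)
            lon = rng.uniform(149.0, 153.6)
        for rep in range(1, cfg.replicates + 1):
            row = {
                "sample_id": f"{site_id}r{rep}",
                "site_id": site_id,
                "replicate": rep,
                "latitude": round(lat + rng.normal(0, 0.01), 5),
                "longitude": round(lon + rng.normal(0, 0.01), 5),
                "region": region,
                "aridity_index": round(ai + rng.normal(0, 0.003), 4),
            }
            k = 0 if region == "arid" else 1
            for name, params in cfg.covariates.items():
                mean, sd = params[k]
                row[name] = round(rng.normal(mean, sd), 4)
            records.append(row)
    meta = pd.DataFrame.from_records(records).set_index("sample_id")
    # replicate jitter can nudge AI over a class boundary; clamp to the window
    meta["aridity_index"] = np.where(
        meta["region"] == "arid",
        meta["aridity_index"].clip(lo + 1e-3, hi - 1e-3),
        meta["aridity_index"].clip(HUMID_AI_MIN + 1e-3, None),
    )

    sample_ids = list(meta.index)
    n = len(sample_ids)
    bact, truth_b = simulate_neutral(
        n, cfg.n_taxa_bacteria, cfg.reads_per_sample, m=cfg.neutral_m,
        seed=int(rng.integers(2**31)), taxon_prefix="bOTU",
    )
    # fungal filtering acts on the aridity index, rescaled to the unit gradient
    ai = meta["aridity_index"].to_numpy(float)
    env = (ai - ai.min()) / (ai.max() - ai.min())
    fungi, truth_f = simulate_niche(
        n, cfg.n_taxa_fungi, cfg.reads_per_sample, env_values=env,
        widths=cfg.niche_sigma, seed=int(rng.integers(2**31)), taxon_prefix="fOTU",
    )
    bact = CommunityMatrix(bact.counts.set_axis(sample_ids, axis=0))
    fungi = CommunityMatrix(fungi.counts.set_axis(sample_ids, axis=0))

    truth = SyntheticTruth(
        seed=seed,
        migration_rate=truth_b.migration_rate,
        metacommunity=truth_b.metacommunity,
        niche_optima=truth_f.niche_optima,
        niche_widths=truth_f.niche_widths,
        region_effects={
            name: params[1][0] - params[0][0] for name, params in cfg.covariates.items()
        },
    )
    return bact, fungi, meta, truth
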