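"""Signed co-occurrence networks: construction, topology, robustness.

Edges are strong, significant Spearman rank correlations between taxa
(default |rho| > 0.6 and Benjamini-Hochberg q < 0.01 across all tested
pairs), carrying the correlation sign.  The absolute-value reading of the
strength threshold is the default: negative links are an explicit analysis
output, which a one-sided rho > 0.6 rule would make impossible;
``use_absolute_rho=False`` exposes the literal one-sided reading.

Stability is probed by random-extinction simulation: remove a fixed fraction
of nodes, count the survivors that keep at least one link, repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import spearmanr, rankdata, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .matrix import CommunityMatrix

__all__ = [
    "SignedNetwork",
    "prevalence_filter",
    "build_network",
    "bh_fdr",
    "topology",
    "negative_link_proportion",
    "robustness",
    "RobustnessResult",
    "compare_robustness",
]

DEFAULT_PREVALENCE_MIN = 1 / 3  # fraction of samples a taxon must occupy


@dataclass
class SignedNetwork:
    """Taxa as nodes; edges carry Spearman rho, BH q-value, and sign."""

    nodes: list
    edges: pd.DataFrame  # columns: source, target, rho, q, sign
    construction_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.edges):
            known = set(self.nodes)
            bad = set(self.edges["source"]) | set(self.edges["target"]) - known
            if not bad <= known:
                raise ValueError(f"edges reference unknown taxa: {bad - known}")
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=row.rho, q=row.q, sign=row.sign)
        return g

    def write_edgelist(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        g = self.to_networkx()
        for node, deg in g.degree():
            g.nodes[node]["degree"] = deg
        nx.write_graphml(g, path)


def prevalence_filter(matrix: CommunityMatrix, min_fraction: float) -> CommunityMatrix:
    """Keep taxa present (count > 0) in at least ``min_fraction`` of samples."""
    if not (0 <= min_fraction <= 1):
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    prevalence = (matrix.counts > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_fraction].index
    if len(keep) == 0:
        raise ValueError(f"prevalence filter at {min_fraction:g} removed every taxon")
    return matrix.select_taxa(keep)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (n > 2)."""
    from scipy.stats import t as t_dist

    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * t_dist.sf(np.abs(t), df=n - 2)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (small n)."""
    from itertools import permutations

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    obs = abs(float(rx @ (ry - ry.mean())))
    hits = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(float(rx @ (np.asarray(perm) - ry.mean()))) >= obs - 1e-12:
            hits += 1
    return hits / total


def build_network(
    matrix: CommunityMatrix,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.01,
    use_absolute_rho: bool = True,
    prevalence_min: float = 0.0,
) -> SignedNetwork:
    """Signed co-occurrence network from all pairwise Spearman correlations.

    All unordered taxon pairs are scored (mid-rank ties); two-sided p-values
    use the t approximation (exact permutation when n <= 9); BH correction
    runs across all tested pairs; an edge is kept iff q < ``q_threshold``
    and |rho| (or rho, if ``use_absolute_rho=False``) > ``rho_threshold``.
    """
    if prevalence_min > 0:
        matrix = prevalence_filter(matrix, prevalence_min)
    n_samples = matrix.n_samples
    if n_samples < 10:
        raise ValueError(f"need >= 10 samples to build a network, got {n_samples}")
    counts = matrix.values().astype(float)
    taxa = matrix.taxon_ids
    n_taxa = len(taxa)

    constant = counts.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa skipped (rho undefined)",
            stacklevel=2,
        )

    rho_full = spearmanr(counts, axis=0).statistic
    if np.isscalar(rho_full):  # two-taxon edge case
        rho_full = np.array([[1.0, rho_full], [rho_full, 1.0]])

    pairs, rhos, ps = [], [], []
    exact = n_samples <= 9
    for i in range(n_taxa):
        if constant[i]:
            continue
        for j in range(i + 1, n_taxa):
            if constant[j]:
                continue
            r = rho_full[i, j]
            if exact:
                p = _exact_spearman_p(counts[:, i], counts[:, j])
            else:
                p = _spearman_pvalues(np.array([r]), n_samples)[0]
            pairs.append((taxa[i], taxa[j]))
            rhos.append(r)
            ps.append(p)

    rhos = np.asarray(rhos)
    qs = bh_fdr(ps) if len(ps) else np.array([])
    strength = np.abs(rhos) if use_absolute_rho else rhos
    keep = (qs < q_threshold) & (strength > rho_threshold) if len(ps) else np.array([], bool)

    edges = pd.DataFrame(
        {
            "source": [pairs[k][0] for k in np.flatnonzero(keep)],
            "target": [pairs[k][1] for k in np.flatnonzero(keep)],
            "rho": rhos[keep],
            "q": qs[keep],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-") if len(edges) else pd.Series(dtype=str)
    return SignedNetwork(
        nodes=list(taxa),
        edges=edges,
        construction_params={
            "rho_threshold": rho_threshold,
            "q_threshold": q_threshold,
            "use_absolute_rho": use_absolute_rho,
            "prevalence_min": prevalence_min,
            "n_samples": n_samples,
            "n_pairs_tested": len(ps),
        },
    )


def topology(net: SignedNetwork) -> dict:
    """Topology metrics on the unweighted, sign-blind graph.

    Per-node degree and harmonic closeness (mean inverse shortest-path
    length, well-defined on disconnected graphs) plus global modularity Q
    from greedy agglomerative optimization.
    """
    if net.n_edges == 0:
        raise ValueError("empty network: no topology to compute")
    g = net.to_networkx()
    # deterministic node order for reproducible greedy tie-breaking
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges()))
    n = h.number_of_nodes()
    degree = pd.Series(dict(h.degree()), name="degree").sort_index()
    harmonic = pd.Series(nx.harmonic_centrality(h), name="closeness") / (n - 1)
    harmonic = harmonic.sort_index()
    communities = nx.algorithms.community.greedy_modularity_communities(h)
    q = nx.algorithms.community.modularity(h, communities)
    return {
        "n_nodes": n,
        "n_edges": h.number_of_edges(),
        "mean_degree": float(degree.mean()),
        "degree": degree,
        "closeness": harmonic,
        "modularity": float(q),
        "n_communities": len(communities),
    }


def negative_link_proportion(net: SignedNetwork) -> float:
    """Fraction of edges whose correlation is negative."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    return float((net.edges["sign"] == "-").mean())


@dataclass
class RobustnessResult:
    """Random-extinction robustness: survivors with >= 1 link, per repetition."""

    removal_fraction: float
    n_repetitions: int
    per_rep: np.ndarray
    mean: float
    sd: float


def robustness(
    net: SignedNetwork,
    removal_fraction: float = 0.5,
    n_repetitions: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Simulate random species extinction and measure surviving connectivity.

    Per repetition: remove floor(f * n) nodes uniformly at random; in the
    induced subgraph a node with no remaining link is extinct; the outcome is
    the proportion of the ORIGINAL n nodes that survive with degree >= 1.
    """
    if not (0 < removal_fraction < 1) and removal_fraction != 1:
        raise ValueError(f"removal_fraction must be in (0, 1], got {removal_fraction}")
    if net.n_nodes < 4:
        raise ValueError("need >= 4 nodes for a robustness simulation")
    rng = np.random.default_rng(seed)
    nodes = np.array(net.nodes, dtype=object)
    n = len(nodes)
    n_remove = int(np.floor(removal_fraction * n))
    # adjacency once; repetitions only index into it
    idx = {t: k for k, t in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for row in net.edges.itertuples(index=False):
        i, j = idx[row.source], idx[row.target]
        adj[i, j] = adj[j, i] = True
    per_rep = np.empty(n_repetitions)
    for r in range(n_repetitions):
        removed = rng.choice(n, size=n_remove, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[removed] = False
        sub = adj[np.ix_(keep, keep)]
        per_rep[r] = (sub.sum(axis=1) > 0).sum() / n
    return RobustnessResult(
        removal_fraction=removal_fraction,
        n_repetitions=n_repetitions,
        per_rep=per_rep,
        mean=float(per_rep.mean()),
        sd=float(per_rep.std(ddof=1)) if n_repetitions > 1 else 0.0,
    )


def compare_robustness(result_a: RobustnessResult, result_b: RobustnessResult) -> float:
    """Two-sided rank-sum p comparing per-repetition robustness distributions."""
    if result_a.removal_fraction != result_b.removal_fraction:
        raise ValueError("robustness results use different removal fractions")
    if min(result_a.n_repetitions, result_b.n_repetitions) < 30:
        raise ValueError("need >= 30 repetitions per result")
    if np.array_equal(result_a.per_rep, result_b.per_rep):
        return 1.0
    res = mannwhitneyu(result_a.per_rep, result_b.per_rep, alternative="two-sided")
    return float(res.pvalue)
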