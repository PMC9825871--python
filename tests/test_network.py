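"""Co-occurrence network construction, topology, robustness."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microassembly import (
    CommunityMatrix,
    bh_fdr,
    build_network,
    compare_robustness,
    negative_link_proportion,
    plant_network,
    prevalence_filter,
    robustness,
    topology,
)
from microassembly.network import SignedNetwork


def _net(nodes, pairs, signs=None):
    signs = signs or ["+"] * len(pairs)
    edges = pd.DataFrame(
        [{"source": a, "target": b, "rho": 0.9 if s == "+" else -0.9,
          "q": 1e-3, "sign": s} for (a, b), s in zip(pairs, signs)]
    )
    if not pairs:
        edges = pd.DataFrame(columns=["source", "target", "rho", "q", "sign"])
    return SignedNetwork(nodes=list(nodes), edges=edges)


def _complete(n, prefix="n"):
    nodes = [f"{prefix}{i}" for i in range(n)]
    return _net(nodes, list(combinations(nodes, 2)))


def _star(n_leaves):
    nodes = ["hub"] + [f"leaf{i}" for i in range(n_leaves)]
    return _net(nodes, [("hub", leaf) for leaf in nodes[1:]])


def _path(n):
    nodes = [f"p{i}" for i in range(n)]
    return _net(nodes, list(zip(nodes, nodes[1:])))


# -- prevalence filter -----------------------------------------------------

def test_prevalence_filter_boundary_cases():
    counts = np.zeros((6, 4), int)
    counts[:, 0] = 1                # everywhere
    counts[:, 1] = 2                # everywhere
    counts[:2, 2] = 1               # 2/6 of samples
    counts[0, 3] = 1                # 1/6
    mat = CommunityMatrix(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(6)],
        columns=["ubi1", "ubi2", "rare", "vrare"],
    ))
    assert prevalence_filter(mat, 0.0).taxon_ids == ["ubi1", "ubi2", "rare", "vrare"]
    assert prevalence_filter(mat, 1 / 3).taxon_ids == ["ubi1", "ubi2", "rare"]
    assert prevalence_filter(mat, 1.0).taxon_ids == ["ubi1", "ubi2"]
    sparse = CommunityMatrix(pd.DataFrame(
        [[1, 0], [0, 1], [1, 0], [0, 1]],
        index=[f"r{i}" for i in range(4)], columns=["u", "v"],
    ))
    with pytest.raises(ValueError, match="removed every taxon"):
        prevalence_filter(sparse, 0.9)


# -- BH-FDR ----------------------------------------------------------------

def _bh_brute(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_fdr_known_values():
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bh_fdr_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 40))
    np.testing.assert_allclose(bh_fdr(p), _bh_brute(p), atol=1e-12)


# -- construction ----------------------------------------------------------

def test_build_network_threshold_and_sign_rules():
    rng = np.random.default_rng(0)
    n = 60
    g = rng.standard_normal(n)
    cols = {
        "pos_a": 50 * g + rng.standard_normal(n) * 5,
        "pos_b": 50 * g + rng.standard_normal(n) * 5,
        "neg": -50 * g + rng.standard_normal(n) * 5,
        "noise1": rng.standard_normal(n) * 30,
        "noise2": rng.standard_normal(n) * 30,
    }
    counts = pd.DataFrame({k: np.round(v - v.min() + 1).astype(int)
                           for k, v in cols.items()},
                          index=[f"s{i}" for i in range(n)])
    net = build_network(CommunityMatrix(counts))
    found = {frozenset((r.source, r.target)): r.sign for r in net.edges.itertuples()}
    assert found[frozenset(("pos_a", "pos_b"))] == "+"
    assert found[frozenset(("pos_a", "neg"))] == "-"
    assert not any("noise1" in k or "noise2" in k for k in found)
    assert (net.edges["q"] < 0.01).all()
    assert (net.edges["rho"].abs() > 0.6).all()
    # literal one-sided reading drops negative edges
    one_sided = build_network(CommunityMatrix(counts), use_absolute_rho=False)
    assert all(r.sign == "+" for r in one_sided.edges.itertuples())


def test_build_network_deterministic():
    mat, _ = plant_network(30, [(4, "+", 0.9)], n_noise_taxa=10, seed=1)
    e1 = build_network(mat).edges
    e2 = build_network(mat).edges
    pd.testing.assert_frame_equal(e1, e2)


def test_constant_taxon_skipped_with_warning():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(1, 50, (15, 4)),
                          index=[f"s{i}" for i in range(15)],
                          columns=list("abcd"))
    counts["const"] = 7
    with pytest.warns(UserWarning, match="constant"):
        net = build_network(CommunityMatrix(counts))
    assert net.construction_params["n_pairs_tested"] == 6  # C(4,2)


# -- topology --------------------------------------------------------------

def test_topology_closed_forms():
    k5 = topology(_complete(5))
    assert set(k5["degree"]) == {4}
    assert set(k5["closeness"]) == {1.0}
    path = topology(_path(3))
    assert path["closeness"]["p1"] == pytest.approx(1.0)
    assert path["closeness"]["p0"] == pytest.approx(0.75)
    two_cliques = _net(
        [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)],
        list(combinations([f"x{i}" for i in range(4)], 2))
        + list(combinations([f"y{i}" for i in range(4)], 2)),
    )
    assert topology(two_cliques)["modularity"] == pytest.approx(0.5)


def test_topology_rejects_empty_network():
    with pytest.raises(ValueError):
        topology(_net(["a", "b"], []))


def test_negative_link_proportion_counting():
    net = _net(list("abcde"),
               [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
               ["+", "-", "+", "+"])
    assert negative_link_proportion(net) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        negative_link_proportion(_net(["a", "b"], []))


# -- robustness ------------------------------------------------------------

def _exact_robustness(net, f):
    """Exhaustive mean over all removal sets of size floor(f*n)."""
    nodes = list(net.nodes)
    n = len(nodes)
    k = int(np.floor(f * n))
    adj = {u: set() for u in nodes}
    for r in net.edges.itertuples(index=False):
        adj[r.source].add(r.target)
        adj[r.target].add(r.source)
    total = 0.0
    count = 0
    for removed in combinations(range(n), k):
        gone = {nodes[i] for i in removed}
        keep = [u for u in nodes if u not in gone]
        surviving = sum(1 for u in keep if adj[u] - gone)
        total += surviving / n
        count += 1
    return total / count


def test_complete_graph_robustness_is_exact():
    res = robustness(_complete(10), removal_fraction=0.5, n_repetitions=50, seed=0)
    assert np.all(res.per_rep == 0.5)


def test_star_enumeration_oracle():
    # star with 4 leaves, remove 2 of 5: exact mean over C(5,2)=10 sets
    star = _star(4)
    exact = _exact_robustness(star, 0.4)
    assert exact == pytest.approx(0.36)
    res = robustness(star, 0.4, n_repetitions=2000, seed=1)
    se = res.sd / np.sqrt(res.n_repetitions)
    assert abs(res.mean - exact) <= 3 * se


@pytest.mark.parametrize("maker, f", [
    (lambda: _complete(6), 0.5),
    (lambda: _complete(8), 0.25),
    (lambda: _star(5), 0.5),
    (lambda: _star(7), 0.3),
    (lambda: _path(6), 0.5),
    (lambda: _path(8), 0.4),
])
def test_monte_carlo_matches_exhaustive_enumeration(maker, f):
    net = maker()
    exact = _exact_robustness(net, f)
    res = robustness(net, f, n_repetitions=2000, seed=2)
    se = max(res.sd / np.sqrt(res.n_repetitions), 1e-9)
    assert abs(res.mean - exact) <= 3 * se


def test_total_extinction_and_bad_fraction():
    star = _star(4)
    res = robustness(star, removal_fraction=1.0, n_repetitions=5, seed=0)
    assert np.all(res.per_rep == 0.0)
    with pytest.raises(ValueError):
        robustness(star, removal_fraction=1.5)


def test_compare_robustness_behaviour():
    k10 = _complete(10)
    s10 = _star(9)
    ra = robustness(k10, 0.3, 100, seed=3)
    rb = robustness(s10, 0.3, 100, seed=4)
    assert compare_robustness(ra, ra) == 1.0
    assert compare_robustness(ra, rb) < 0.001
    rb_bad = robustness(s10, 0.5, 100, seed=4)
    with pytest.raises(ValueError):
        compare_robustness(ra, rb_bad)


def test_planted_blocks_recovered_with_correct_sign_balance():
    spec = [(5, "+", 0.9), (5, "+", 0.9), (5, "-", 0.9)]
    mat, truth = plant_network(50, spec, n_noise_taxa=60, seed=0)
    net = build_network(mat)
    planted = {frozenset((a, b)): s for a, b, s in truth.planted_edges}
    found = {frozenset((r.source, r.target)): r.sign for r in net.edges.itertuples()}
    tp = sum(1 for k, s in found.items() if planted.get(k) == s)
    assert tp / len(found) >= 0.9           # precision
    assert tp / len(planted) >= 0.8         # recall
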