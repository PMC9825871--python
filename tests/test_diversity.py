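"""Diversity indices, ordination, PERMANOVA, distance decay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microassembly import (
    CommunityMatrix,
    bray_curtis,
    distance_decay,
    group_compare,
    haversine_km,
    pcoa,
    permanova,
    pielou,
    shannon,
    simulate_neutral,
)


# -- alpha diversity -------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [
        ((10, 10, 10, 10), np.log(4)),
        ((7, 0, 0), 0.0),
        ((1, 2, 3), 1.0114042647073518),  # -sum p ln p at p=(1/6, 2/6, 3/6)
    ],
)
def test_shannon_known_values(counts, expected):
    assert shannon(counts) == pytest.approx(expected, abs=1e-10)


def test_shannon_rejects_empty():
    with pytest.raises(ValueError):
        shannon([0, 0])


def test_pielou_uniform_is_one_and_known_value():
    assert pielou([3, 3, 3, 3, 3]) == pytest.approx(1.0)
    assert pielou([1, 2, 3]) == pytest.approx(1.0114042647073518 / np.log(3))
    with pytest.raises(ValueError):
        pielou([5, 0])


# -- Bray-Curtis -----------------------------------------------------------

def _bc_brute(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x + y).sum()


def test_bray_curtis_identity_disjoint_and_raw_value():
    mat = CommunityMatrix(pd.DataFrame(
        [[1, 1, 0], [1, 1, 0], [0, 0, 7]],
        index=["a", "b", "c"], columns=["t1", "t2", "t3"],
    ))
    d = bray_curtis(mat)
    assert d.loc["a", "b"] == pytest.approx(0.0)
    assert d.loc["a", "c"] == pytest.approx(1.0)
    raw = bray_curtis(
        CommunityMatrix(pd.DataFrame([[1, 1, 0], [0, 1, 1]],
                                     index=["x", "y"], columns=list("pqr"))),
        transform="raw",
    )
    assert raw.loc["x", "y"] == pytest.approx(0.5)  # 1 - 2*1/4


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bray_curtis_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, size=(6, 5))
    counts[counts.sum(axis=1) == 0, 0] = 1
    mat = CommunityMatrix(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(6)], columns=[f"t{j}" for j in range(5)]
    ))
    d = bray_curtis(mat, transform="raw").to_numpy()
    for i in range(6):
        for j in range(6):
            assert d[i, j] == pytest.approx(_bc_brute(counts[i], counts[j]), abs=1e-12)


# -- PCoA ------------------------------------------------------------------

def test_pcoa_equilateral_triangle_geometry():
    labels = ["a", "b", "c"]
    d = pd.DataFrame(1.0 - np.eye(3), index=labels, columns=labels)
    res = pcoa(d, n_axes=2)
    eig = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(eig) == 2 and eig[0] == pytest.approx(eig[1], rel=1e-8)
    coords = res.coordinates.to_numpy()
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-8)


def test_pcoa_recovers_euclidean_configuration():
    # classical scaling on a Euclidean distance matrix reproduces distances
    rng = np.random.default_rng(0)
    points = rng.normal(size=(8, 3))
    from scipy.spatial.distance import pdist, squareform

    labels = [f"s{i}" for i in range(8)]
    d = pd.DataFrame(squareform(pdist(points)), index=labels, columns=labels)
    res = pcoa(d, n_axes=3)
    emb = squareform(pdist(res.coordinates.to_numpy()))
    assert np.abs(emb - d.to_numpy()).max() < 1e-8
    # a line of points is ordered along axis 1
    line = np.array([[0.0], [1.0], [2.5], [4.0]])
    dl = pd.DataFrame(squareform(pdist(line)), index=list("wxyz"), columns=list("wxyz"))
    axis1 = pcoa(dl, n_axes=1).coordinates["PCo1"].to_numpy()
    assert np.all(np.diff(axis1) > 0) or np.all(np.diff(axis1) < 0)


def test_pcoa_duplicate_samples_coincide():
    labels = ["a", "b", "c"]
    m = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
    res = pcoa(pd.DataFrame(m, index=labels, columns=labels), n_axes=1)
    assert res.coordinates.loc["a", "PCo1"] == pytest.approx(
        res.coordinates.loc["b", "PCo1"], abs=1e-10
    )


# -- PERMANOVA -------------------------------------------------------------

def test_permanova_matches_skbio_and_is_seed_reproducible():
    from skbio.stats.distance import DistanceMatrix as SkDM, permanova as sk_permanova

    mat, _ = simulate_neutral(12, 30, 500, m=0.2, seed=3)
    d = bray_curtis(mat)
    groups = ["a"] * 6 + ["b"] * 6
    mine = permanova(d, groups, n_permutations=999, seed=5)
    again = permanova(d, groups, n_permutations=999, seed=5)
    assert mine.p_value == again.p_value  # bit-exact under a seed
    sk = sk_permanova(SkDM(d.to_numpy(), ids=list(map(str, d.index))), groups)
    assert mine.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-10)


def test_permanova_maximal_separation_reaches_floor():
    # disjoint supports: F_obs beats every permuted relabelling, so p sits
    # at the permutation floor (large enough n that no permutation re-draws
    # the original split)
    rng = np.random.default_rng(0)
    counts = np.zeros((20, 4), int)
    counts[:10, :2] = rng.integers(3, 9, (10, 2))
    counts[10:, 2:] = rng.integers(3, 9, (10, 2))
    mat = CommunityMatrix(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(20)], columns=list("wxyz")
    ))
    res = permanova(bray_curtis(mat), ["g1"] * 10 + ["g2"] * 10,
                    n_permutations=199, seed=1)
    assert res.p_value == pytest.approx(1 / 200)


def test_permanova_r2_invariant_to_sample_duplication():
    # duplicating every sample (with its label) changes F but not R2
    rng = np.random.default_rng(2)
    base = rng.random((6, 6))
    d0 = np.triu(base, 1)
    d0 = d0 + d0.T
    labels6 = [f"s{i}" for i in range(6)]
    groups6 = ["a", "a", "a", "b", "b", "b"]
    r_small = permanova(pd.DataFrame(d0, index=labels6, columns=labels6),
                        groups6, n_permutations=9, seed=0)
    big = np.kron(np.ones((2, 2)), d0)
    labels12 = [f"s{i}{r}" for r in "xy" for i in range(6)]
    big_df = pd.DataFrame(big, index=labels12, columns=labels12)
    r_big = permanova(big_df, groups6 * 2, n_permutations=9, seed=0)
    assert r_big.R2 == pytest.approx(r_small.R2, rel=1e-10)


def test_permanova_rejects_singleton_group():
    labels = ["a", "b", "c"]
    d = pd.DataFrame(1 - np.eye(3), index=labels, columns=labels)
    with pytest.raises(ValueError):
        permanova(d, ["g1", "g1", "g2"], seed=0)


# -- rank-sum comparison ---------------------------------------------------

def test_group_compare_known_exact_values():
    # disjoint (1,2,3) vs (10,11,12): 2 of 20 arrangements as extreme
    p = group_compare([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
    assert p == pytest.approx(0.1)
    # identical multisets: observed rank sum equals its expectation
    p = group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert p == pytest.approx(1.0)


def test_group_compare_invariant_to_location_shift():
    rng = np.random.default_rng(4)
    values = rng.normal(size=14)
    labels = ["a"] * 7 + ["b"] * 7
    assert group_compare(values, labels) == pytest.approx(
        group_compare(values + 100.0, labels)
    )


def test_group_compare_requires_two_groups():
    with pytest.raises(ValueError):
        group_compare([1, 2, 3], ["a", "a", "a"])


# -- geographic distance and decay ----------------------------------------

def test_haversine_known_values():
    assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
    assert haversine_km(0, 0, 0, 1) == pytest.approx(111.195, abs=1e-3)
    assert haversine_km(-20, 140, -30, 150) == pytest.approx(
        haversine_km(-30, 150, -20, 140)
    )


def test_distance_decay_perfect_linear_fit():
    # construct similarities exactly linear in great-circle distance
    lats = [0.0, 0.0, 0.0, 0.0]
    lons = [0.0, 1.0, 2.0, 3.0]
    labels = [f"s{i}" for i in range(4)]
    meta = pd.DataFrame({"latitude": lats, "longitude": lons}, index=labels)
    km01 = haversine_km(0, 0, 0, 1)
    d = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            d[i, j] = 1.0 - (1.0 - 0.001 * abs(lons[i] - lons[j]) * km01 / 111.195)
    fit = distance_decay(pd.DataFrame(d, index=labels, columns=labels), meta)
    assert fit.R2 == pytest.approx(1.0, abs=1e-10)
    assert fit.slope < 0


def test_distance_decay_rejects_colocated_samples():
    labels = ["a", "b", "c"]
    meta = pd.DataFrame({"latitude": [1.0] * 3, "longitude": [2.0] * 3}, index=labels)
    d = pd.DataFrame(1 - np.eye(3), index=labels, columns=labels)
    with pytest.raises(ValueError, match="co-located"):
        distance_decay(d, meta)
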