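"""Bray-Curtis distances, complete-linkage agglomeration, SIMPROF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import copeind as ci
from copeind.clustering import bray_curtis, complete_linkage, cut, simprof
from copeind.errors import ValidationError


def _sim_from(frame):
    return bray_curtis(frame)


def test_self_distance_zero_and_symmetry():
    frame = pd.DataFrame(
        [[22.78, 34.19, 7.07, 8.33], [26.52, 34.27, 6.63, 8.39]],
        index=["a", "b"],
    )
    sim = _sim_from(frame)
    assert np.allclose(np.diag(sim.dissimilarity), 0.0)
    assert np.allclose(sim.dissimilarity, sim.dissimilarity.T)


def test_disjoint_support_distance_one():
    frame = pd.DataFrame([[1.0, 0, 0, 0], [0, 1.0, 0, 0]], index=["a", "b"])
    sim = _sim_from(frame)
    assert sim.dissimilarity[0, 1] == pytest.approx(1.0)


def test_group_profile_distance_hand_value():
    """d between the cold-water and oceanic group mean profiles is
    4.32/148.18 ~ 0.0292 (similarity ~ 97.08%)."""
    frame = pd.DataFrame(
        [[22.78, 34.19, 7.07, 8.33], [26.52, 34.27, 6.63, 8.39]],
        index=["A", "C"],
    )
    sim = _sim_from(frame)
    assert sim.dissimilarity[0, 1] == pytest.approx(4.32 / 148.18, abs=1e-6)
    assert sim.similarity[0, 1] == pytest.approx(97.08, abs=0.01)


def test_negative_values_rejected_with_advice():
    frame = pd.DataFrame([[1.0, -2.0], [3.0, 4.0]], index=["a", "b"])
    with pytest.raises(ValidationError, match="standardize"):
        bray_curtis(frame)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.1, max_value=50.0))
def test_bray_curtis_bounds_and_scale_invariance(seed, c):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(rng.uniform(0.1, 30.0, (5, 4)),
                         index=[f"s{i}" for i in range(5)])
    d1 = bray_curtis(frame).dissimilarity
    assert ((d1 >= -1e-12) & (d1 <= 1 + 1e-12)).all()
    d2 = bray_curtis(frame * c).dissimilarity
    assert np.allclose(d1, d2)


def test_three_point_linkage_exhaustive():
    """d(1,2)=0.1, d(1,3)=0.9, d(2,3)=0.8: first merge (1,2) at 0.1, final
    merge at the complete-linkage maximum 0.9."""
    d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
    sim = ci.SimilarityMatrix(("p1", "p2", "p3"), d)
    tree = complete_linkage(sim)
    assert tree[0, 2] == pytest.approx(0.1)
    assert sorted(tree[0, :2].astype(int)) == [0, 1]
    assert tree[1, 2] == pytest.approx(0.9)


def test_equal_distances_equal_heights():
    d = np.full((4, 4), 0.3)
    np.fill_diagonal(d, 0.0)
    tree = complete_linkage(ci.SimilarityMatrix(tuple("abcd"), d))
    assert np.allclose(tree[:, 2], 0.3)


def test_complete_linkage_heights_are_max_within_cluster_distance(
        default_survey):
    _, env, _, _ = default_survey
    sim = bray_curtis(env.data)
    tree = complete_linkage(sim)
    from scipy.cluster.hierarchy import fcluster

    assert (np.diff(tree[:, 2]) >= -1e-15).all()  # monotone heights
    # at every merge the height equals the max pairwise d inside the new cluster
    n = len(sim.station_ids)
    members = {i: [i] for i in range(n)}
    for m, row in enumerate(tree):
        a, b = int(row[0]), int(row[1])
        new = members[a] + members[b]
        members[n + m] = new
        dmax = max(sim.dissimilarity[i, j] for i in new for j in new)
        assert row[2] == pytest.approx(dmax)


def test_cut_extremes_and_labels(default_survey):
    _, env, _, _ = default_survey
    sim = bray_curtis(env.data)
    tree = complete_linkage(sim)
    n = len(sim.station_ids)
    singletons = cut(tree, sim, n, env=env.data)
    assert singletons.n_groups == n
    one = cut(tree, sim, 1, env=env.data)
    assert one.n_groups == 1
    gsim = ci.group_similarity(sim, one)
    iu = np.triu_indices(n, k=1)
    assert gsim.iloc[0]["mean_similarity"] == pytest.approx(
        sim.similarity[iu].mean()
    )
    # singleton convention: similarity 100, flagged
    gs = ci.group_similarity(sim, singletons)
    assert (gs["mean_similarity"] == 100.0).all()
    assert gs["singleton"].all()


def test_groups_labelled_by_descending_oxygen(default_survey):
    _, env, _, truth = default_survey
    res = ci.EnvClustering(env).fit(k=3, simprof_permutations=0)
    do = env.data["dissolved_oxygen"].groupby(res.partition.labels).mean()
    assert do["A"] > do["B"] > do["C"]


def test_synthetic_three_group_fixture_recovered():
    """Well-separated profiles: cutting at k=3 recovers the planted groups
    and within-group similarities land in the high-90s band."""
    prof = {
        g: dict(ci.DEFAULT_ENV_PROFILES[g], temperature=(t, 0.3))
        for g, t in zip("ABC", (21.5, 24.5, 27.5))
    }
    _, env, _, truth = ci.generate(ci.SyntheticDesign(seed=3, env_profiles=prof))
    res = ci.EnvClustering(env).fit(k=3, simprof_permutations=0)
    assert truth.partition.same_groups(res.partition)
    assert (res.group_similarity["mean_similarity"] > 97.0).all()


def test_simprof_requires_three_stations():
    frame = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
    with pytest.raises(ValidationError, match="at least 3"):
        simprof(frame)


def test_simprof_identical_stations_pi_zero():
    frame = pd.DataFrame([[22.0, 34.0, 7.0, 8.3]] * 5,
                         index=[f"s{i}" for i in range(5)])
    res = simprof(frame, n_perm_expected=99, n_perm_test=199, seed=0)
    assert res.pi == pytest.approx(0.0, abs=1e-9)
    assert res.p_value > 0.9


def test_simprof_detects_planted_structure():
    """Two well-separated sub-blobs: p <= 0.01 at 999 permutations."""
    rng = np.random.default_rng(5)
    blob1 = rng.normal([20.0, 34.0, 7.0, 8.3], 0.05, (5, 4))
    blob2 = rng.normal([27.0, 34.3, 6.5, 8.4], 0.05, (5, 4))
    frame = pd.DataFrame(np.vstack([blob1, blob2]),
                         index=[f"s{i}" for i in range(10)])
    res = simprof(frame, n_perm_expected=999, n_perm_test=999, seed=1)
    assert res.p_value <= 0.01


def test_newick_export_contains_all_stations(default_survey):
    _, env, _, _ = default_survey
    res = ci.EnvClustering(env).fit(k=3, simprof_permutations=0)
    nwk = res.to_newick()
    assert nwk.endswith(";")
    for sid in env.station_ids:
        assert sid in nwk
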