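import itertools

import numpy as np
import pandas as pd
import pytest

from guildfill import functional_diversity as fdiv
from guildfill import synthetic
from guildfill.core_data import TraitTable

from conftest import random_ultrametric


def brute_force_fd(community, model):
    """Independent oracle: union of edges on paths between community leaves.

    Builds explicit root-paths per leaf; the spanning subtree is the union of
    symmetric differences of root-paths over all leaf pairs.
    """
    n = model.n_species
    Z = model.Z
    parent = {}
    for i in range(n - 1):
        parent[int(Z[i, 0])] = n + i
        parent[int(Z[i, 1])] = n + i
    heights = np.concatenate([np.zeros(n), Z[:, 2]])

    def root_path(leaf):
        path = []
        node = leaf
        while node in parent:
            path.append(node)  # the edge from node up to its parent
            node = parent[node]
        return set(path)

    idx = model.index_of(community)
    edges = set()
    for a, b in itertools.combinations(idx, 2):
        edges |= root_path(a) ^ root_path(b)
    length = sum(heights[parent[e]] - heights[e] for e in edges)
    return length / model.total_branch_length


def test_gower_hand_example():
    values = pd.DataFrame({"mass": [10.0, 15.0, 20.0], "diet": [1, 2, 3]}, index=["A", "B", "C"])
    traits = TraitTable(values, {"mass": "continuous", "diet": "ordinal"}, {"diet": [1, 2, 3]})
    D = fdiv.gower_distance(traits)
    assert D.loc["A", "B"] == pytest.approx(0.5)  # (0.5 + 0.5)/2
    assert D.loc["A", "C"] == pytest.approx(1.0)
    assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)


def test_gower_identical_and_maximal_rows():
    values = pd.DataFrame({"a": [1.0, 1.0], "b": [3.0, 3.0]}, index=["X", "Y"])
    with pytest.warns(UserWarning, match="zero range"):
        # identical rows also mean zero-range traits; distance must be 0
        traits = TraitTable(values, {"a": "continuous", "b": "continuous"})
        assert fdiv.gower_distance(traits).loc["X", "Y"] == 0.0
    values2 = pd.DataFrame({"a": [0.0, 1.0], "b": [5.0, 9.0]}, index=["X", "Y"])
    traits2 = TraitTable(values2, {"a": "continuous", "b": "continuous"})
    assert fdiv.gower_distance(traits2).loc["X", "Y"] == pytest.approx(1.0)


def test_gower_categorical_mismatch_and_missing_values():
    values = pd.DataFrame(
        {"colour": ["red", "blue", "red"], "mass": [1.0, np.nan, 3.0]},
        index=["A", "B", "C"],
    )
    traits = TraitTable(values, {"colour": "categorical", "mass": "continuous"})
    D = fdiv.gower_distance(traits)
    # A-B share only colour (mismatch) -> 1; A-C share both: (0 + 1)/2
    assert D.loc["A", "B"] == pytest.approx(1.0)
    assert D.loc["A", "C"] == pytest.approx(0.5)


def test_gower_disjoint_traits_error():
    values = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]}, index=["X", "Y"])
    traits = TraitTable(values, {"a": "continuous", "b": "continuous"})
    with pytest.raises(ValueError, match="shares no measured traits"):
        fdiv.gower_distance(traits)


def test_toy_tree_structure(toy_tree):
    assert toy_tree.total_branch_length == pytest.approx(5.0)
    assert toy_tree.cophenetic_c == pytest.approx(1.0)  # input was ultrametric
    assert not toy_tree.c_flagged


def test_fd_toy_values(toy_tree):
    assert fdiv.fd(["A", "B", "C"], toy_tree) == pytest.approx(1.0)
    assert fdiv.fd(["A", "B"], toy_tree) == pytest.approx(0.4)
    assert fdiv.fd(["A", "C"], toy_tree) == pytest.approx(0.8)
    assert fdiv.fd(["A"], toy_tree) == 0.0
    assert fdiv.fd([], toy_tree) == 0.0


def test_two_species_dendrogram_flagged():
    D = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]], index=["A", "B"], columns=["A", "B"])
    model = fdiv.build_dendrogram(D, "average")
    assert model.c_flagged and model.cophenetic_c == 1.0
    assert model.total_branch_length == pytest.approx(1.2)  # two pendants of 0.6


def test_fd_matches_brute_force_on_random_trees():
    """Masked-edge FD equals the path-union oracle on all subsets of 6-leaf trees."""
    rng = np.random.default_rng(30)
    for _ in range(5):
        D = random_ultrametric(rng, 6)
        model = fdiv.build_dendrogram(D, "average")
        labels = model.labels
        for size in range(2, 7):
            for community in itertools.combinations(labels, size):
                assert fdiv.fd(community, model) == pytest.approx(
                    brute_force_fd(community, model), abs=1e-10
                )


def test_fd_is_monotone_in_species():
    rng = np.random.default_rng(31)
    D = random_ultrametric(rng, 8)
    model = fdiv.build_dendrogram(D, "average")
    labels = list(model.labels)
    for _ in range(30):
        k = rng.integers(1, 8)
        comm = list(rng.choice(labels, size=k, replace=False))
        extra = rng.choice([s for s in labels if s not in comm])
        assert fdiv.fd(comm + [extra], model) >= fdiv.fd(comm, model) - 1e-12


def test_select_linkage_prefers_average_on_ties_and_max_c(toy_tree):
    rng = np.random.default_rng(32)
    D = random_ultrametric(rng, 5)
    model = fdiv.select_linkage(D)  # ultrametric: all linkages tie at c=1
    assert model.linkage_method == "average"
    for _ in range(5):
        n = 7
        M = rng.uniform(0.1, 1.0, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        Df = pd.DataFrame(M, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])
        best = fdiv.select_linkage(Df)
        for method in fdiv.LINKAGES:
            assert best.cophenetic_c >= fdiv.build_dendrogram(Df, method).cophenetic_c - 1e-9


def test_null_ses_full_pool_is_flagged(toy_tree):
    presence = pd.DataFrame(
        [[1, 1, 1]], index=pd.Index(["P1"], name="point_id"), columns=["A", "B", "C"]
    )
    out = fdiv.null_ses(presence, toy_tree, null="uniform", n_iter=50, seed=1)
    row = out.iloc[0]
    assert row["fd_obs"] == pytest.approx(1.0)
    assert row["null_mean"] == pytest.approx(1.0)
    assert row["ses_flagged"] and np.isnan(row["ses"])


def test_weighted_sampling_matches_weights():
    """Inclusion frequencies track weights within 3 binomial SEs at 10^4 draws."""
    rng = np.random.default_rng(33)
    weights = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
    draws = fdiv._sample_without_replacement(rng, weights, 1, 10_000)
    freq = draws.mean(axis=0)
    se = np.sqrt(weights * (1 - weights) / 10_000)
    assert np.all(np.abs(freq - weights) < 3 * se + 1e-3)
    # size-2 draws: every row has exactly 2 distinct species
    draws2 = fdiv._sample_without_replacement(rng, weights, 2, 1000)
    assert np.all(draws2.sum(axis=1) == 2)


def test_frequency_null_equals_uniform_when_frequencies_equal():
    rng = np.random.default_rng(34)
    D = random_ultrametric(rng, 6)
    model = fdiv.build_dendrogram(D, "average")
    # every species present equally often -> frequency weights are uniform
    presence = pd.DataFrame(
        np.tile(np.eye(6, dtype=int), (2, 1)),
        index=pd.Index([f"P{i}" for i in range(12)], name="point_id"),
        columns=model.labels,
    )
    presence.iloc[:, :] = 0
    for i in range(12):
        presence.iloc[i, [i % 6, (i + 1) % 6]] = 1
    uni = fdiv.null_ses(presence, model, null="uniform", n_iter=4000, seed=7)
    freq = fdiv.null_ses(presence, model, null="frequency", n_iter=4000, seed=7)
    assert np.allclose(uni["null_mean"], freq["null_mean"], atol=0.02)


def test_packing_correlation_edge_cases(toy_tree):
    table = pd.DataFrame({"ses": [1.0, 1.0, 1.0], "richness": [1, 2, 3]})
    with pytest.raises(ValueError):
        fdiv.packing_correlation(table)
    table2 = pd.DataFrame({"ses": [-1.0, -2.0, -3.0], "richness": [1.0, 2.0, 3.0]})
    r, p = fdiv.packing_correlation(table2)
    assert r == pytest.approx(-1.0)


def test_packing_correlation_recovers_programmed_filtering():
    """Richness-dependent trait filtering produces the negative SES-richness trend."""
    rng = np.random.default_rng(35)
    traits = synthetic.generate_traits(12, 4, seed=35)
    D = fdiv.gower_distance(traits)
    model = fdiv.build_dendrogram(D, "average")
    labels = model.labels
    # order species along the dendrogram; rich communities take functionally
    # adjacent (similar) species, poor communities spread out
    order = np.argsort(model.edge_leaves[: len(labels)].argmax(axis=1))
    rows = []
    for i in range(120):
        S = int(rng.integers(2, 10))
        if S >= 6:  # rich: a contiguous block of similar species
            start = rng.integers(0, len(labels) - S)
            chosen = [labels[j] for j in range(start, start + S)]
        else:  # poor: uniformly spread
            chosen = list(rng.choice(labels, size=S, replace=False))
        row = {sp: int(sp in chosen) for sp in labels}
        rows.append(row)
    presence = pd.DataFrame(rows, index=pd.Index([f"P{i}" for i in range(120)], name="point_id"))
    out = fdiv.null_ses(presence[labels], model, null="uniform", n_iter=400, seed=36)
    r, p = fdiv.packing_correlation(out)
    assert r < 0
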