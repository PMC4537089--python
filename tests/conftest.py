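import numpy as np
import pandas as pd
import pytest

from guildfill import synthetic
from guildfill.core_data import AVAILABILITY_COLUMNS, SurveyDataset
from guildfill.functional_diversity import build_dendrogram


def make_point_counts(rows):
    """Helper: point-count table from (site, point, habitat, avail-dict) tuples."""
    out = []
    for site, point, habitat, avail in rows:
        rec = {
            "site_id": site, "point_id": point, "year": 2011,
            "habitat_class": habitat, "x": 0.0, "y": 0.0,
            **{col: 0.1 for col in AVAILABILITY_COLUMNS},
        }
        for res, v in avail.items():
            rec[f"avail_{res}"] = v
        out.append(rec)
    return pd.DataFrame(out)


def make_observations(rows):
    """Helper: observation table from (point, species, dist, flock, activity, resource)."""
    return pd.DataFrame(
        rows,
        columns=["point_id", "species_id", "distance_m", "flock_size", "activity", "resource_used"],
    )


def make_species(ids, statuses=None, masses=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "species_id": ids,
            "common_name": ids,
            "status": statuses or ["native"] * n,
            "body_mass_g": masses or [20.0] * n,
        }
    )


@pytest.fixture
def tiny_dataset():
    """Two point counts, two species, four observations."""
    pc = make_point_counts(
        [
            ("S1", "P1", "rice", {"emergent": 0.2, "trees_bushes": 0.0}),
            ("S1", "P2", "wetland", {"emergent": 0.4, "trees_bushes": 0.3}),
        ]
    )
    obs = make_observations(
        [
            ("P1", "A", 12.0, 3, "feeding", "forbs"),
            ("P1", "B", 40.0, 1, "shelter", "emergent"),
            ("P2", "A", 25.0, 2, "feeding", "rough_grass"),
            ("P2", "A", 60.0, 1, "other", "none"),
        ]
    )
    return SurveyDataset(
        species=make_species(["A", "B"], ["native", "nonnative"], [25.0, 10.0]),
        point_counts=pc,
        observations=obs,
    )


@pytest.fixture(scope="session")
def small_survey():
    """A seeded mid-sized synthetic survey shared across read-only tests."""
    cfg = synthetic.paper_like_config(n_rice_sites=15, n_other_sites=4)
    dataset, truth = synthetic.generate_survey(cfg, seed=42)
    return dataset, truth, cfg


@pytest.fixture
def toy_tree():
    """Three-leaf ultrametric tree: A,B merge at height 1, C joins at height 2.

    Total branch length 5 (pendants 1+1+2, internal 1).
    """
    D = pd.DataFrame(
        [[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 2.0, 0.0]],
        index=["A", "B", "C"], columns=["A", "B", "C"],
    )
    return build_dendrogram(D, "average")


def random_ultrametric(rng, n_leaves):
    """Random ultrametric distance matrix via a random coalescent-style tree."""
    # merge random clusters at strictly increasing heights
    clusters = [[i] for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    h = 0.0
    while len(clusters) > 1:
        h += rng.uniform(0.2, 1.0)
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[a, b] = D[b, a] = h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = [f"sp{i}" for i in range(n_leaves)]
    return pd.DataFrame(D, index=labels, columns=labels)
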