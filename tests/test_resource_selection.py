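import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildfill import resource_selection as rs
from guildfill import synthetic
from guildfill.core_data import SurveyDataset
from guildfill.inference import wilcoxon_mw

from conftest import make_observations, make_point_counts, make_species


@pytest.mark.parametrize(
    "u,a,expected",
    [
        (0.3, 0.3, 0.0),  # use proportional to availability
        (1.0, 0.25, 1.0),  # exclusive use
        (0.0, 0.25, -1.0),  # complete avoidance
        (0.8, 0.5, 0.6),  # hand evaluation of (u-a)/(u+a-2ua)
    ],
)
def test_jacobs_index_closed_form(u, a, expected):
    assert rs.jacobs_index(u, a) == pytest.approx(expected)


@pytest.mark.parametrize("a", [0.0, 1.0])
def test_jacobs_index_undefined_at_degenerate_availability(a):
    with pytest.raises(rs.UndefinedSelectionError):
        rs.jacobs_index(0.5, a)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    u=st.floats(0.0, 1.0, allow_nan=False),
    a=st.floats(0.01, 0.99, allow_nan=False),
)
def test_jacobs_index_symmetry_and_bounds(u, a):
    J = rs.jacobs_index(u, a)
    assert -1.0 <= J <= 1.0
    assert J == pytest.approx(-rs.jacobs_index(1.0 - u, 1.0 - a), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=st.floats(0.05, 0.95), u1=st.floats(0.0, 1.0), u2=st.floats(0.0, 1.0))
def test_jacobs_index_monotone_in_use(a, u1, u2):
    lo, hi = sorted([u1, u2])
    assert rs.jacobs_index(lo, a) <= rs.jacobs_index(hi, a) + 1e-12


def _two_point_dataset():
    pc = make_point_counts(
        [
            ("S1", "P1", "rice", {"emergent": 0.2}),
            ("S1", "P2", "rice", {"emergent": 0.4}),
            ("S2", "P3", "wetland", {"emergent": 0.9}),
        ]
    )
    obs = make_observations(
        [
            ("P1", "A", 10.0, 1, "shelter", "emergent"),
            ("P2", "A", 10.0, 1, "shelter", "trees_bushes"),
        ]
    )
    return SurveyDataset(species=make_species(["A", "B"]), point_counts=pc, observations=obs)


def test_availability_occupied_is_mean_over_occupied_points():
    ds = _two_point_dataset()
    assert rs.availability(ds, "A", "emergent", mode="occupied") == pytest.approx(0.3)
    # mode=all also counts the unoccupied P3
    assert rs.availability(ds, "A", "emergent", mode="all") == pytest.approx(0.5)


def test_availability_modes_agree_when_availability_constant():
    pc = make_point_counts([("S1", f"P{i}", "rice", {"emergent": 0.3}) for i in range(4)])
    obs = make_observations([("P0", "A", 10.0, 1, "shelter", "emergent")])
    ds = SurveyDataset(species=make_species(["A"]), point_counts=pc, observations=obs)
    occ = rs.availability(ds, "A", "emergent", mode="occupied")
    assert occ == pytest.approx(rs.availability(ds, "A", "emergent", mode="all"))


def test_availability_unrecorded_species_errors():
    ds = _two_point_dataset()
    with pytest.raises(ValueError, match="B"):
        rs.availability(ds, "B", "emergent", mode="occupied")


def test_selection_table_recovers_programmed_preference():
    """A species sheltering only in emergent vegetation converges to J -> 1."""
    cfg = synthetic.ScenarioConfig(
        species=[
            synthetic.SpeciesConfig(
                species_id="X", status="nonnative", body_mass_g=10.0,
                lambda_rice=3.0, lambda_other=3.0, sigma0=1e6, mean_flock=1.0,
                activity_probs={"shelter": 1.0},
                resource_probs={"shelter": {"emergent": 1.0}},
            )
        ],
        n_rice_sites=15, n_other_sites=3, site_effect_sd=0.0,
    )
    ds, _ = synthetic.generate_survey(cfg, seed=20)
    table = rs.selection_table(ds, "shelter").set_index("resource")
    # u is slightly below 1 only because flocks at points with no emergent
    # vegetation at all record "none" rather than an unavailable resource
    assert table.loc["emergent", "u"] > 0.95
    assert table.loc["emergent", "J"] > 0.8
    assert not table.loc["emergent", "low_n"]


def test_selection_table_indifference_centres_on_zero():
    """If use mirrors availability (u* = a*), J stays near zero."""
    rng = np.random.default_rng(21)
    a_star = 0.3
    pc = make_point_counts(
        [("S1", f"P{i}", "rice", {"emergent": a_star, "trees_bushes": 1 - a_star}) for i in range(40)]
    )
    obs_rows = [
        (f"P{i}", "A", 10.0, 1, "shelter",
         "emergent" if rng.random() < a_star else "trees_bushes")
        for i in range(40)
        for _ in range(10)
    ]
    ds = SurveyDataset(
        species=make_species(["A"]), point_counts=pc, observations=make_observations(obs_rows)
    )
    table = rs.selection_table(ds, "shelter").set_index("resource")
    assert abs(table.loc["emergent", "J"]) < 0.15


def test_selection_table_excludes_other_activity_and_flags_low_n(tiny_dataset):
    table = rs.selection_table(tiny_dataset, "feeding")
    # species A has 2 feeding observations (the "other" one is excluded)
    a_rows = table[table["species_id"] == "A"]
    assert set(a_rows["n_obs"]) == {2}
    assert a_rows["low_n"].all()
    with pytest.raises(ValueError):
        rs.selection_table(tiny_dataset, "other")


def test_compare_selection_delegates_to_rank_test():
    ds = _two_point_dataset()
    table = pd.DataFrame(
        {
            "species_id": ["A", "B", "C", "D"],
            "activity": "shelter",
            "resource": "emergent",
            "u": 0.5, "a": 0.3,
            "J": [0.1, 0.2, 0.7, 0.9],
            "n_obs": 10, "low_n": False,
        }
    )
    sp = make_species(["A", "B", "C", "D"], ["native", "native", "nonnative", "nonnative"])
    ds2 = SurveyDataset(species=sp, point_counts=ds.point_counts, observations=make_observations([]))
    res = rs.compare_selection(table, ds2, "emergent", "shelter")
    direct = wilcoxon_mw([0.1, 0.2], [0.7, 0.9])
    assert res.W == direct.W and res.p == direct.p
    assert res.W == 0  # natives fully below non-natives


def test_cwm_hand_values_and_invariances():
    q = pd.DataFrame(
        {
            "quadrat_id": "Q1", "habitat": "rice_margin", "point_id": "",
            "plant_species": ["a", "b"], "cover_pct": [0.6, 0.4], "capacity_g": [2.0, 5.0],
        }
    )
    assert rs.cwm_capacity(q).cwm_capacity_g == pytest.approx(3.2)
    q100 = q.assign(cover_pct=q["cover_pct"] * 100)
    assert rs.cwm_capacity(q100).cwm_capacity_g == pytest.approx(3.2)
    single = q.iloc[[0]]
    assert rs.cwm_capacity(single).cwm_capacity_g == pytest.approx(2.0)
    # bounded by min/max capacity
    rng = np.random.default_rng(22)
    caps = rng.uniform(1, 8, 5)
    qr = pd.DataFrame(
        {
            "quadrat_id": "Q2", "habitat": "rice_margin", "point_id": "",
            "plant_species": list("abcde"), "cover_pct": rng.uniform(0.1, 1, 5),
            "capacity_g": caps,
        }
    )
    cwm = rs.cwm_capacity(qr).cwm_capacity_g
    assert caps.min() <= cwm <= caps.max()


def test_cwm_missing_capacity_errors():
    q = pd.DataFrame(
        {
            "quadrat_id": "Q1", "habitat": "rice_margin", "point_id": "",
            "plant_species": ["a", "b"], "cover_pct": [0.6, 0.4], "capacity_g": [2.0, np.nan],
        }
    )
    with pytest.raises(ValueError, match="b"):
        rs.cwm_capacity(q)
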