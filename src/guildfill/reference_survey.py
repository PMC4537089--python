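"""Occupancy summary of the published Iberian rice-field seed-eating bird survey.

A point-count survey of seed-eating birds across rice-growing landscapes of
Portugal and western Spain recorded 17 species (4 non-native, 13 native) in
456 point counts — 200 in rice fields and 256 in adjacent open habitats across
61 sites. The per-species occupancy counts printed with that survey are
transcribed here so occupancy-level quantities (e.g. in how many point counts
a species was present) can be recomputed through the pipeline's
community-matrix machinery.

:func:`occupancy_dataset` expands the summary into a
:class:`~guildfill.core_data.SurveyDataset` that reproduces the per-species,
per-habitat presence pattern EXACTLY but is otherwise synthetic: distances,
flock sizes, activities and the within-habitat arrangement of presences are
placeholders, so only occupancy-level results are meaningful on it.
"""

from __future__ import annotations

import pandas as pd

from .core_data import AVAILABILITY_COLUMNS, SurveyDataset

N_RICE_POINTS = 200
N_OTHER_POINTS = 256
N_SITES = 61

#: species_id, common name, status, sites present, rice point counts present,
#: other point counts present
SPECIES_OCCUPANCY: tuple[tuple[str, str, str, int, int, int], ...] = (
    ("BHW", "black-headed weaver", "nonnative", 8, 11, 8),
    ("BUL", "bullfinch", "native", 1, 0, 1),
    ("CHA", "chaffinch", "native", 13, 6, 21),
    ("CWA", "common waxbill", "nonnative", 56, 82, 94),
    ("COB", "corn bunting", "native", 35, 67, 75),
    ("GOL", "goldfinch", "native", 54, 69, 96),
    ("GRE", "greenfinch", "native", 42, 43, 83),
    ("HAW", "hawfinch", "native", 1, 1, 0),
    ("HOS", "house sparrow", "native", 60, 129, 151),
    ("LIN", "linnet", "native", 44, 38, 50),
    ("RAV", "red avadavat", "nonnative", 11, 13, 8),
    ("REB", "reed bunting", "native", 2, 1, 3),
    ("SER", "serin", "native", 50, 56, 106),
    ("SIS", "siskin", "native", 1, 0, 2),
    ("SPS", "spanish sparrow", "native", 6, 1, 9),
    ("TRS", "tree sparrow", "native", 14, 11, 16),
    ("YCB", "yellow-crowned bishop", "nonnative", 21, 54, 13),
)


def occupancy_summary() -> pd.DataFrame:
    """The transcribed occupancy table as a DataFrame."""
    return pd.DataFrame(
        SPECIES_OCCUPANCY,
        columns=["species_id", "common_name", "status", "n_sites", "n_rice_present", "n_other_present"],
    )


def occupancy_dataset() -> SurveyDataset:
    """Expand the occupancy summary into an occupancy-faithful synthetic dataset.

    456 point counts (200 rice, 256 other) are laid out over 61 nominal sites;
    each species is marked present (one placeholder observation) in exactly its
    recorded number of rice and other point counts. Distances (10 m), flock
    sizes (1), activities ("other") and availabilities are placeholders.
    """
    pc_rows = []
    for i in range(N_RICE_POINTS + N_OTHER_POINTS):
        habitat = "rice" if i < N_RICE_POINTS else "agriculture"
        pc_rows.append(
            {
                "site_id": f"S{(i % N_SITES) + 1:02d}",
                "point_id": f"P{i + 1:03d}",
                "year": 2011,
                "habitat_class": habitat,
                "x": float(i),
                "y": 0.0,
                **{col: 0.0 for col in AVAILABILITY_COLUMNS},
            }
        )
    point_counts = pd.DataFrame(pc_rows)
    rice_ids = point_counts.loc[point_counts["habitat_class"] == "rice", "point_id"].tolist()
    other_ids = point_counts.loc[point_counts["habitat_class"] != "rice", "point_id"].tolist()

    obs_rows = []
    for sid, _, _, _, n_rice, n_other in SPECIES_OCCUPANCY:
        for pid in rice_ids[:n_rice] + other_ids[:n_other]:
            obs_rows.append(
                {
                    "point_id": pid,
                    "species_id": sid,
                    "distance_m": 10.0,
                    "flock_size": 1,
                    "activity": "other",
                    "resource_used": "none",
                }
            )
    observations = pd.DataFrame(obs_rows)
    species = occupancy_summary()[["species_id", "common_name", "status"]].copy()
    species["body_mass_g"] = 1.0  # placeholder; masses are not part of the occupancy summary
    return SurveyDataset(species=species, point_counts=point_counts, observations=observations)
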