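"""Data model for point-count surveys, species traits, quadrats and gradient scores.

The survey data model mirrors the structure of a point-transect bird survey:
sites contain point counts, point counts contain observations of flocks, and
each point count carries the local availability of four vegetation resource
classes measured on a 49-cell recording grid (so raw availabilities are
multiples of 1/49).

All tables are plain pandas DataFrames with documented columns; the
:class:`SurveyDataset` container validates referential integrity between them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Vegetation resource classes recorded on the availability grid.
RESOURCE_CLASSES: tuple[str, ...] = ("forbs", "rough_grass", "emergent", "trees_bushes")

#: Activities recorded per observed flock.
ACTIVITIES: tuple[str, ...] = ("feeding", "shelter", "other")

#: Habitat classes a point count can fall in.
HABITAT_CLASSES: tuple[str, ...] = ("rice", "agriculture", "river", "wetland")

#: Truncation radius of the point counts, metres.
TRUNCATION_M: float = 100.0

#: Number of cells on the resource recording grid at each point count.
GRID_CELLS: int = 49

AVAILABILITY_COLUMNS = tuple(f"avail_{r}" for r in RESOURCE_CLASSES)

POINT_COUNT_COLUMNS = (
    "site_id", "point_id", "year", "habitat_class", "x", "y", *AVAILABILITY_COLUMNS,
)
OBSERVATION_COLUMNS = (
    "point_id", "species_id", "distance_m", "flock_size", "activity", "resource_used",
)
SPECIES_COLUMNS = ("species_id", "common_name", "status", "body_mass_g")
QUADRAT_COLUMNS = (
    "quadrat_id", "habitat", "point_id", "plant_species", "cover_pct", "capacity_g",
)


class SurveyFormatError(ValueError):
    """A tabular input does not match the documented column layout."""


class SurveyReferenceError(ValueError):
    """A row refers to a species or point count that does not exist."""


class StateError(RuntimeError):
    """An operation was requested before a prerequisite pipeline stage ran."""


@dataclasses.dataclass
class TraitTable:
    """Species-by-trait matrix with mixed continuous/ordinal/categorical traits.

    Parameters
    ----------
    values
        DataFrame indexed by species_id, one column per trait. Missing values
        (NaN) are permitted; Gower distance averages over pairwise-present
        traits.
    kinds
        Mapping trait name -> one of ``{"continuous", "ordinal", "categorical"}``.
    levels
        For ordinal traits, the ordered level set (low to high). Ordinal values
        are scored as equally spaced ranks within this set.
    """

    values: pd.DataFrame
    kinds: Mapping[str, str]
    levels: Mapping[str, Sequence] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait in self.values.columns:
            kind = self.kinds.get(trait)
            if kind not in ("continuous", "ordinal", "categorical"):
                raise SurveyFormatError(f"trait {trait!r} has unknown kind {kind!r}")
            if kind == "ordinal":
                lv = list(self.levels.get(trait, []))
                if not lv:
                    raise SurveyFormatError(f"ordinal trait {trait!r} lacks a level set")
                col = self.values[trait].dropna()
                bad = set(col) - set(lv)
                if bad:
                    raise SurveyFormatError(
                        f"ordinal trait {trait!r} has values outside its level set: {sorted(map(str, bad))}"
                    )
        if len(self.values) and self.values.isna().all(axis=1).any():
            empty = self.values.index[self.values.isna().all(axis=1)].tolist()
            raise SurveyFormatError(f"species with no trait values: {empty}")

    @property
    def species(self) -> list:
        return list(self.values.index)

    def numeric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Encode traits numerically for Gower distance.

        Ordinal traits become 0..k-1 ranks, continuous stay as-is, categorical
        are passed through as object codes handled separately.

        Returns ``(matrix, trait_names, kinds_per_column)``.
        """
        cols = []
        names = []
        kinds = []
        for trait in self.values.columns:
            kind = self.kinds[trait]
            col = self.values[trait]
            if kind == "ordinal":
                rank = {lvl: float(i) for i, lvl in enumerate(self.levels[trait])}
                cols.append(col.map(rank).to_numpy(dtype=float))
            elif kind == "continuous":
                cols.append(col.to_numpy(dtype=float))
            else:  # categorical: factorize; NaN -> nan code
                codes, _ = pd.factorize(col, use_na_sentinel=True)
                arr = codes.astype(float)
                arr[codes < 0] = np.nan
                cols.append(arr)
            names.append(trait)
            kinds.append(kind)
        mat = np.column_stack(cols) if cols else np.empty((len(self.values), 0))
        return mat, names, kinds

    def to_csv(self, path: str | Path) -> None:
        meta = pd.DataFrame(
            {
                "trait": list(self.values.columns),
                "kind": [self.kinds[t] for t in self.values.columns],
                "levels": ["|".join(map(str, self.levels.get(t, []))) for t in self.values.columns],
            }
        )
        path = Path(path)
        self.values.to_csv(path, index_label="species_id")
        meta.to_csv(path.with_suffix(".meta.csv"), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        path = Path(path)
        values = pd.read_csv(path, index_col="species_id")
        meta = pd.read_csv(path.with_suffix(".meta.csv"))
        kinds = dict(zip(meta["trait"], meta["kind"]))

        def _parse(tok: str):
            for cast in (int, float):
                try:
                    return cast(tok)
                except ValueError:
                    continue
            return tok

        levels = {
            t: [_parse(tok) for tok in lv.split("|")]
            for t, lv in zip(meta["trait"], meta["levels"].fillna(""))
            if lv
        }
        return cls(values=values, kinds=kinds, levels=levels)


@dataclasses.dataclass
class SurveyDataset:
    """A validated survey: species pool, point counts, observations, quadrats.

    ``densities`` is attached by the detectability stage
    (:func:`guildfill.detectability.estimate_density`); community matrices on
    the density scale are unavailable before then.
    """

    species: pd.DataFrame
    point_counts: pd.DataFrame
    observations: pd.DataFrame
    quadrats: pd.DataFrame | None = None
    densities: pd.DataFrame | None = None
    n_rejected_distance: int = 0

    def __post_init__(self) -> None:
        _require_columns(self.species, SPECIES_COLUMNS, "species")
        _require_columns(self.point_counts, POINT_COUNT_COLUMNS, "point_counts")
        _require_columns(self.observations, OBSERVATION_COLUMNS, "observations")
        if self.quadrats is not None:
            _require_columns(self.quadrats, QUADRAT_COLUMNS, "quadrats")

    def check_references(self) -> None:
        """Raise :class:`SurveyReferenceError` on dangling species/point references."""
        unknown_sp = set(self.observations["species_id"]) - set(self.species["species_id"])
        if unknown_sp:
            raise SurveyReferenceError(f"unresolvable species codes: {sorted(unknown_sp)}")
        unknown_pt = set(self.observations["point_id"]) - set(self.point_counts["point_id"])
        if unknown_pt:
            raise SurveyReferenceError(f"unresolvable point ids: {sorted(unknown_pt)}")

    @property
    def is_rice(self) -> pd.Series:
        """Boolean per point count: is it in a rice field."""
        return self.point_counts["habitat_class"].eq("rice")

    def availability_matrix(self) -> pd.DataFrame:
        """Point-count x resource-class availability proportions."""
        out = self.point_counts.set_index("point_id")[list(AVAILABILITY_COLUMNS)]
        out.columns = list(RESOURCE_CLASSES)
        return out

    def attach_densities(self, densities: pd.DataFrame) -> None:
        self.densities = densities

    def equals(self, other: "SurveyDataset") -> bool:
        same = (
            self.species.reset_index(drop=True).equals(other.species.reset_index(drop=True))
            and self.point_counts.reset_index(drop=True).equals(other.point_counts.reset_index(drop=True))
            and self.observations.reset_index(drop=True).equals(other.observations.reset_index(drop=True))
        )
        if self.quadrats is None or other.quadrats is None:
            return same and (self.quadrats is None) == (other.quadrats is None)
        return same and self.quadrats.reset_index(drop=True).equals(other.quadrats.reset_index(drop=True))


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"table {table!r} is missing columns: {missing}")


def read_survey(
    point_count_path: str | Path,
    observation_path: str | Path,
    species_path: str | Path,
    quadrat_path: str | Path | None = None,
    column_map: Mapping[str, Mapping[str, str]] | None = None,
    truncation_m: float = TRUNCATION_M,
) -> SurveyDataset:
    """Read the canonical survey CSVs into a validated :class:`SurveyDataset`.

    ``column_map`` optionally maps external headers to canonical ones per
    table (keys ``point_counts``, ``observations``, ``species``, ``quadrats``),
    so externally deposited tables can be imported without editing files.
    Observations beyond ``truncation_m`` are dropped; the count of dropped rows
    is recorded on the dataset as ``n_rejected_distance``.
    """
    column_map = column_map or {}

    def _read(path, table):
        # round_trip float parsing keeps write/read the identity to the bit
        df = pd.read_csv(path, float_precision="round_trip")
        mapping = column_map.get(table, {})
        return df.rename(columns=dict(mapping))

    species = _read(species_path, "species")
    point_counts = _read(point_count_path, "point_counts")
    observations = _read(observation_path, "observations")
    quadrats = _read(quadrat_path, "quadrats") if quadrat_path is not None else None

    _require_columns(observations, OBSERVATION_COLUMNS, "observations")
    too_far = observations["distance_m"] > truncation_m
    n_rejected = int(too_far.sum())
    observations = observations.loc[~too_far].reset_index(drop=True)

    dataset = SurveyDataset(
        species=species,
        point_counts=point_counts,
        observations=observations,
        quadrats=quadrats,
        n_rejected_distance=n_rejected,
    )
    dataset.check_references()
    return dataset


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset's tables as the canonical CSVs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "point_counts": out_dir / "point_counts.csv",
        "observations": out_dir / "observations.csv",
        "species": out_dir / "species.csv",
    }
    dataset.point_counts.to_csv(paths["point_counts"], index=False)
    dataset.observations.to_csv(paths["observations"], index=False)
    dataset.species.to_csv(paths["species"], index=False)
    if dataset.quadrats is not None:
        paths["quadrats"] = out_dir / "quadrats.csv"
        dataset.quadrats.to_csv(paths["quadrats"], index=False)
    return paths


def build_community_matrix(dataset: SurveyDataset, value: str = "presence") -> pd.DataFrame:
    """Point-count x species matrix of presence (0/1) or estimated density.

    Presence is what the functional-diversity stage consumes (the FD measure
    is defined on presence-absence communities); density requires the
    detectability stage to have attached density estimates first.
    """
    points = dataset.point_counts["point_id"]
    species = dataset.species["species_id"]
    if value == "presence":
        obs = dataset.observations
        mat = pd.crosstab(obs["point_id"], obs["species_id"]).clip(upper=1)
    elif value == "density":
        if dataset.densities is None:
            raise StateError(
                "density community matrix requested before density estimation; "
                "run the detectability stage and attach_densities() first"
            )
        mat = dataset.densities.pivot_table(
            index="point_id", columns="species_id", values="density", aggfunc="sum"
        )
    else:
        raise ValueError(f"value must be 'presence' or 'density', got {value!r}")
    mat = mat.reindex(index=points, columns=species, fill_value=0).fillna(0.0)
    if value == "presence":
        mat = mat.astype(int)
    mat.index.name = "point_id"
    mat.columns.name = "species_id"
    return mat


def validate(dataset: SurveyDataset) -> list[str]:
    """Non-mutating invariant check; returns a list of human-readable violations."""
    report: list[str] = []
    sp = dataset.species
    for _, row in sp.iterrows():
        if not row["body_mass_g"] > 0:
            report.append(f"species {row['species_id']}: body_mass_g must be > 0")
        if row["status"] not in ("native", "nonnative"):
            report.append(f"species {row['species_id']}: status {row['status']!r} invalid")
    pc = dataset.point_counts
    for col in AVAILABILITY_COLUMNS:
        bad = pc.loc[(pc[col] < 0) | (pc[col] > 1), "point_id"]
        for pid in bad:
            report.append(f"point {pid}: availability out of [0,1] in {col}")
    for _, row in pc.iterrows():
        if row["habitat_class"] not in HABITAT_CLASSES:
            report.append(f"point {row['point_id']}: habitat_class {row['habitat_class']!r} invalid")
    if pc["point_id"].duplicated().any():
        dups = pc.loc[pc["point_id"].duplicated(), "point_id"].tolist()
        report.append(f"duplicated point ids: {dups}")
    obs = dataset.observations
    known_points = set(pc["point_id"])
    known_species = set(sp["species_id"])
    for _, row in obs.iterrows():
        if row["point_id"] not in known_points:
            report.append(f"observation references unknown point {row['point_id']}")
        if row["species_id"] not in known_species:
            report.append(f"observation references unknown species {row['species_id']}")
        if not (0 <= row["distance_m"] <= TRUNCATION_M):
            report.append(
                f"observation at point {row['point_id']}: distance {row['distance_m']} outside [0, {TRUNCATION_M:g}]"
            )
        if row["flock_size"] < 1:
            report.append(f"observation at point {row['point_id']}: flock_size < 1")
        if row["activity"] not in ACTIVITIES:
            report.append(f"observation at point {row['point_id']}: activity {row['activity']!r} invalid")
    return report
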