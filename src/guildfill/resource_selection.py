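"""Jacobs-index resource selection and community-weighted mean plant capacity.

Selection of a resource class by a species is quantified with Jacobs index

    J = (u - a) / (u + a - 2 u a),

where u is the proportion of that species' observations of a given activity
(feeding or shelter) in which the resource was used, and a is the availability
of the resource. Availability is, by default, averaged over the point counts
where the species was recorded ("occupied" mode), which removes the effect of
where the species chooses to be from the within-point selection signal; the
"all" mode averages over every point count instead and so folds occupancy
effects back in.

J ranges from -1 (complete avoidance) through 0 (use proportional to
availability) to +1 (exclusive use).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_data import RESOURCE_CLASSES, SurveyDataset
from .inference import WilcoxonResult, wilcoxon_mw


class UndefinedSelectionError(ValueError):
    """Jacobs index is undefined when availability is exactly 0 or 1."""


def jacobs_index(u: float, a: float) -> float:
    """Jacobs selectivity index J = (u - a)/(u + a - 2ua).

    ``u`` is the proportion of use in [0, 1]; ``a`` the availability, strictly
    inside (0, 1) (at 0 or 1 there is no scope for selection and the index is
    undefined).
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must be in [0,1], got {u}")
    if not 0.0 < a < 1.0:
        raise UndefinedSelectionError(f"availability must be strictly inside (0,1), got {a}")
    denom = u + a - 2.0 * u * a
    if denom == 0.0:  # only possible at the (0,0)/(1,1) corners, excluded above
        return 0.0
    # clip: at u in {0,1} rounding can overshoot the exact +/-1 bound by 1 ulp
    return float(np.clip((u - a) / denom, -1.0, 1.0))


def availability(
    dataset: SurveyDataset,
    species_id: str,
    resource: str,
    mode: str = "occupied",
) -> float:
    """Mean availability proportion of ``resource`` over a set of point counts.

    mode="occupied": average over the point counts where the species was
    recorded (the default, isolating within-point selection);
    mode="all": average over every point count.
    Per-point proportions are averaged unweighted.
    """
    if resource not in RESOURCE_CLASSES:
        raise ValueError(f"unknown resource class {resource!r}")
    col = f"avail_{resource}"
    if mode == "all":
        return float(dataset.point_counts[col].mean())
    if mode != "occupied":
        raise ValueError(f"mode must be 'occupied' or 'all', got {mode!r}")
    occupied = set(dataset.observations.loc[dataset.observations["species_id"] == species_id, "point_id"])
    if not occupied:
        raise ValueError(f"species {species_id!r} recorded in no point counts; occupied-mode availability undefined")
    sel = dataset.point_counts["point_id"].isin(occupied)
    return float(dataset.point_counts.loc[sel, col].mean())


def selection_table(
    dataset: SurveyDataset,
    activity: str,
    mode: str = "occupied",
    min_obs: int = 5,
    weight_by_flock: bool = False,
) -> pd.DataFrame:
    """Per-species x resource Jacobs indices for one activity.

    ``u`` counts recorded flocks (each group is one selection event) unless
    ``weight_by_flock`` weights events by flock size. Observations with
    activity "other" never enter. Rows where a species has fewer than
    ``min_obs`` activity observations are flagged (``low_n`` True), not
    dropped. Resources whose availability is exactly 0 or 1 for the species'
    point-count set yield NaN J (selection undefined there).
    """
    if activity not in ("feeding", "shelter"):
        raise ValueError("activity must be 'feeding' or 'shelter'")
    obs = dataset.observations
    act = obs.loc[obs["activity"] == activity]
    rows = []
    for species_id, group in act.groupby("species_id", sort=False):
        weights = group["flock_size"].to_numpy(dtype=float) if weight_by_flock else np.ones(len(group))
        total = weights.sum()
        n_obs = len(group)
        for resource in RESOURCE_CLASSES:
            used = weights[(group["resource_used"] == resource).to_numpy()].sum()
            u = used / total if total > 0 else np.nan
            a = availability(dataset, str(species_id), resource, mode=mode)
            try:
                J = jacobs_index(float(u), a)
            except UndefinedSelectionError:
                J = np.nan
            rows.append(
                {
                    "species_id": species_id,
                    "activity": activity,
                    "resource": resource,
                    "u": u,
                    "a": a,
                    "J": J,
                    "n_obs": n_obs,
                    "low_n": n_obs < min_obs,
                }
            )
    return pd.DataFrame(rows, columns=["species_id", "activity", "resource", "u", "a", "J", "n_obs", "low_n"])


def compare_selection(
    table: pd.DataFrame,
    dataset: SurveyDataset,
    resource: str,
    activity: str,
    include_low_n: bool = True,
) -> WilcoxonResult:
    """Rank-sum comparison of per-species J between native and non-native species.

    Native species form group 1 (so W follows the native-first convention of
    the group comparisons elsewhere in the pipeline).
    """
    status = dataset.species.set_index("species_id")["status"]
    sel = table.loc[(table["resource"] == resource) & (table["activity"] == activity)].dropna(subset=["J"])
    if not include_low_n:
        sel = sel.loc[~sel["low_n"]]
    groups = sel["species_id"].map(status)
    native = sel.loc[groups.eq("native"), "J"].to_numpy(dtype=float)
    nonnative = sel.loc[groups.eq("nonnative"), "J"].to_numpy(dtype=float)
    if len(native) == 0 or len(nonnative) == 0:
        raise ValueError("need at least one species with an estimate in each status group")
    return wilcoxon_mw(native, nonnative)


@dataclasses.dataclass
class CWMResult:
    """Community-weighted mean weight-holding capacity of one quadrat."""

    quadrat_id: str
    habitat: str
    cwm_capacity_g: float


def cwm_capacity(quadrat: pd.DataFrame) -> CWMResult:
    """CWM capacity of a single quadrat's long-format rows.

    cwm = sum(cover_k * capacity_k) / sum(cover_k); invariant to rescaling the
    covers (percent vs proportion) and bounded by the min/max capacity present.
    """
    if quadrat["quadrat_id"].nunique() != 1:
        raise ValueError("cwm_capacity expects the rows of exactly one quadrat")
    cover = quadrat["cover_pct"].to_numpy(dtype=float)
    cap = quadrat["capacity_g"].to_numpy(dtype=float)
    if np.any(pd.isna(cap)):
        missing = quadrat.loc[pd.isna(quadrat["capacity_g"]), "plant_species"].tolist()
        raise ValueError(f"missing capacity for covered species: {missing}")
    if cover.sum() <= 0:
        raise ValueError("total cover must be > 0")
    return CWMResult(
        quadrat_id=str(quadrat["quadrat_id"].iloc[0]),
        habitat=str(quadrat["habitat"].iloc[0]),
        cwm_capacity_g=float(np.sum(cover * cap) / np.sum(cover)),
    )


def cwm_table(quadrats: pd.DataFrame) -> pd.DataFrame:
    """CWM capacity for every quadrat in a long-format quadrat table."""
    rows = [dataclasses.asdict(cwm_capacity(g)) for _, g in quadrats.groupby("quadrat_id", sort=False)]
    return pd.DataFrame(rows)
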