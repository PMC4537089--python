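"""Habitat-association profiles along ordered environmental gradients.

Species' qualitative habitat associations are coded as integer scores per
habitat type (0 = no association, 1 = weak, 2 = strong) and projected onto
ordered environmental gradients — a wet-to-dry gradient with four categories
and an open-to-closed (structural) gradient with six. A habitat type may span
more than one gradient position; the score of a species at a gradient
position is the maximum of its scores over all habitats mapped there.

Group (native vs non-native) profiles of mean score +/- SE along a gradient
show where in environmental space the two groups' associations diverge most.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_SCORES = (0, 1, 2)


@dataclasses.dataclass
class Gradient:
    """An ordered environmental gradient with a habitat-to-position mapping."""

    name: str
    categories: tuple[str, ...]  # ordered low -> high
    habitat_map: Mapping[str, Sequence[str]]  # habitat type -> categories it spans

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("gradient categories must be unique")
        for habitat, cats in self.habitat_map.items():
            unknown = set(cats) - set(self.categories)
            if unknown:
                raise ValueError(f"habitat {habitat!r} maps to unknown categories {sorted(unknown)}")
            if not cats:
                raise ValueError(f"habitat {habitat!r} maps to no category")

    def habitats_at(self, position: str) -> list[str]:
        if position not in self.categories:
            raise ValueError(f"unknown gradient position {position!r}")
        return [h for h, cats in self.habitat_map.items() if position in cats]


def wet_dry_gradient(habitat_map: Mapping[str, Sequence[str]]) -> Gradient:
    """The four-category hydrological gradient."""
    return Gradient(
        name="wet_dry",
        categories=("extensive_wetland", "linear_fragmented_wetland", "damp", "dry"),
        habitat_map=habitat_map,
    )


def open_closed_gradient(habitat_map: Mapping[str, Sequence[str]]) -> Gradient:
    """The six-category vegetation-structure gradient, open to forested."""
    return Gradient(
        name="open_closed",
        categories=(
            "low_vegetation",
            "low_with_taller_patches",
            "tall_nonwoody",
            "mixed_mostly_nonwoody",
            "mixed_mostly_woody",
            "forest",
        ),
        habitat_map=habitat_map,
    )


def validate_scores(scores: pd.DataFrame) -> None:
    """Association scores are integers in {0, 1, 2} (species x habitat)."""
    arr = scores.to_numpy()
    if not np.isin(arr, VALID_SCORES).all():
        bad = sorted(set(arr.ravel()) - set(VALID_SCORES))
        raise ValueError(f"association scores must be in {VALID_SCORES}; found {bad}")


def position_score(species: str, position: str, scores: pd.DataFrame, gradient: Gradient) -> int:
    """Overall association score of a species at one gradient position.

    The maximum score across all habitats mapped to that position; 0 when no
    scored habitat maps there (adding unscored habitats cannot change it).
    """
    habitats = gradient.habitats_at(position)
    habitats = [h for h in habitats if h in scores.columns]
    if not habitats:
        return 0
    return int(scores.loc[species, habitats].max())


def species_profile(species: str, scores: pd.DataFrame, gradient: Gradient) -> pd.Series:
    """Association score of one species at every gradient position."""
    return pd.Series(
        {pos: position_score(species, pos, scores, gradient) for pos in gradient.categories},
        name=species,
    )


def group_profile(scores: pd.DataFrame, gradient: Gradient, species_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE association per gradient position for each status group.

    Returns a DataFrame indexed by gradient position with columns
    ``native_mean``, ``native_se``, ``nonnative_mean``, ``nonnative_se``.
    SE is NaN for single-species groups (undefined, flagged by NaN).
    """
    validate_scores(scores)
    status = species_table.set_index("species_id")["status"]
    profiles = pd.DataFrame({sp: species_profile(sp, scores, gradient) for sp in scores.index}).T
    out = {}
    for group in ("native", "nonnative"):
        members = [sp for sp in profiles.index if status.get(sp) == group]
        if not members:
            raise ValueError(f"no species in group {group!r}")
        sub = profiles.loc[members]
        out[f"{group}_mean"] = sub.mean(axis=0)
        out[f"{group}_se"] = (
            sub.std(axis=0, ddof=1) / np.sqrt(len(members)) if len(members) > 1
            else pd.Series(np.nan, index=profiles.columns)
        )
    result = pd.DataFrame(out)
    result.index.name = "position"
    return result.loc[list(gradient.categories)]


def max_divergence_position(profile: pd.DataFrame) -> list[str]:
    """Gradient position(s) where |nonnative mean - native mean| is largest.

    All tied positions are returned (in gradient order); identical profiles tie
    everywhere at zero divergence.
    """
    div = (profile["nonnative_mean"] - profile["native_mean"]).abs()
    best = div.max()
    return [str(pos) for pos in profile.index[np.isclose(div, best)]]
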