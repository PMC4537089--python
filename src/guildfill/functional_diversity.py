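"""Dendrogram-based functional diversity with randomization null models.

The trait matrix (mixed continuous / ordinal / categorical) is converted to a
Gower distance matrix, clustered into an ultrametric dendrogram (linkage chosen
by cophenetic correlation with the source distances), and the functional
diversity (FD) of a community is the total branch length of the subtree
spanning the community's species divided by the total branch length of the
full-pool dendrogram. FD is therefore in [0, 1], equals 1 for the full pool
and 0 for a singleton (no branches connect one leaf to itself).

Observed FD is standardized against null communities of equal species richness
drawn from the pool either uniformly or with probability proportional to each
species' observed occurrence frequency:

    SES = (FD_obs - mean(FD_null)) / sd(FD_null).

Negative SES indicates functional under-dispersion (habitat filtering /
species packing), positive SES over-dispersion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import scipy.stats

from .core_data import TraitTable

LINKAGES = ("single", "complete", "average")


def gower_distance(traits: TraitTable) -> pd.DataFrame:
    """Gower distance matrix over species.

    Per-trait dissimilarity: continuous and ordinal-as-rank traits contribute
    |x_i - x_j| / range; categorical traits contribute 0/1 mismatch. The
    distance is the mean over traits where both species have a value
    (pairwise-available averaging). Traits with zero range carry no
    information and are excluded with a warning; a species pair sharing no
    traits at all is an error.
    """
    if len(traits.values) < 2:
        raise ValueError("need >= 2 species")
    mat, names, kinds = traits.numeric_matrix()
    n, t = mat.shape
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(t):
        col = mat[:, j]
        present = ~np.isnan(col)
        both = np.outer(present, present)
        if kinds[j] == "categorical":
            diff = (col[:, None] != col[None, :]).astype(float)
        else:
            rng_ = np.nanmax(col) - np.nanmin(col)
            if not rng_ > 0:
                # constant trait: zero dissimilarity for every pair (it still
                # counts as shared information, so identical rows stay at 0)
                warnings.warn(f"trait {names[j]!r} has zero range; contributes no dissimilarity")
                diff = np.zeros((n, n))
            else:
                diff = np.abs(col[:, None] - col[None, :]) / rng_
        diff = np.where(both, diff, 0.0)
        num += diff
        den += both.astype(float)
    off = ~np.eye(n, dtype=bool)
    if np.any(den[off] == 0):
        i, j = np.argwhere((den == 0) & off)[0]
        raise ValueError(
            f"species pair ({traits.species[i]}, {traits.species[j]}) shares no measured traits"
        )
    with np.errstate(invalid="ignore"):
        D = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=traits.species, columns=traits.species)


@dataclasses.dataclass
class DendrogramModel:
    """Ultrametric merge tree over the full species pool.

    Internally stores, for every non-root node, its pendant edge length and the
    set of leaves below it, which makes branch-length FD a masked sum.
    """

    labels: list[str]
    linkage_method: str
    Z: np.ndarray  # scipy linkage matrix
    cophenetic_c: float
    c_flagged: bool  # True when c is undefined (2 species) and set to 1 by convention
    edge_lengths: np.ndarray  # (n_edges,) pendant edge length per non-root node
    edge_leaves: np.ndarray  # (n_edges, n_leaves) bool leaf membership below each edge
    total_branch_length: float

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def index_of(self, species) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.labels)}
        try:
            return np.array([pos[s] for s in species], dtype=int)
        except KeyError as err:
            raise KeyError(f"species {err} not in the dendrogram's pool") from None

    def to_newick(self) -> str:
        """Newick string with branch lengths, for external inspection."""
        n = self.n_species
        heights = np.concatenate([np.zeros(n), self.Z[:, 2]])

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_h - 0.0:.6g}"
            row = self.Z[node - n]
            h = heights[node]
            left = render(int(row[0]), h)
            right = render(int(row[1]), h)
            return f"({left},{right}):{parent_h - h:.6g}"

        root = 2 * n - 2
        row = self.Z[-1]
        h = heights[root]
        return f"({render(int(row[0]), h)},{render(int(row[1]), h)});"


def build_dendrogram(distance: pd.DataFrame, linkage: str = "average") -> DendrogramModel:
    """Agglomerative dendrogram from a distance matrix.

    The cophenetic correlation ``c`` (Pearson r between the source distances
    and the merge-height distances) measures how faithfully the tree
    represents the distance matrix. For two species every linkage gives a
    perfect single merge; c is then undefined and reported as 1, flagged.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = np.asarray(distance, dtype=float)
    n = len(D)
    if n < 2:
        raise ValueError("need >= 2 species")
    labels = list(distance.index) if isinstance(distance, pd.DataFrame) else [str(i) for i in range(n)]
    condensed = scipy.spatial.distance.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    if n == 2:
        c, c_flagged = 1.0, True
    else:
        c, _ = sch.cophenet(Z, condensed)
        c, c_flagged = float(c), False

    # per-node pendant edges: length = height(parent) - height(node)
    heights = np.concatenate([np.zeros(n), Z[:, 2]])
    parent = np.full(2 * n - 1, -1, dtype=int)
    leaves = np.zeros((2 * n - 1, n), dtype=bool)
    leaves[np.arange(n), np.arange(n)] = True
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        parent[a] = parent[b] = n + i
        leaves[n + i] = leaves[a] | leaves[b]
    nodes = np.arange(2 * n - 2)  # all but the root
    lengths = heights[parent[nodes]] - heights[nodes]
    if np.any(lengths < -1e-9):
        raise ValueError("non-monotone linkage heights; dendrogram is not ultrametric")
    lengths = np.maximum(lengths, 0.0)
    return DendrogramModel(
        labels=labels,
        linkage_method=linkage,
        Z=Z,
        cophenetic_c=c,
        c_flagged=c_flagged,
        edge_lengths=lengths,
        edge_leaves=leaves[nodes],
        total_branch_length=float(lengths.sum()),
    )


def select_linkage(distance: pd.DataFrame) -> DendrogramModel:
    """Build single/complete/average dendrograms and keep the highest-c one.

    Ties (within 1e-9) resolve to average linkage.
    """
    models = {m: build_dendrogram(distance, m) for m in LINKAGES}
    best_c = max(m.cophenetic_c for m in models.values())
    if models["average"].cophenetic_c >= best_c - 1e-9:
        return models["average"]
    return max(models.values(), key=lambda m: m.cophenetic_c)


def fd(community, model: DendrogramModel) -> float:
    """Branch-length functional diversity of one community, in [0, 1].

    The numerator is the total length of the edges of the full-pool dendrogram
    that lie on a path between two community members (the spanning subtree of
    the community's leaves); the denominator is the pool's total branch
    length. Empty and singleton communities span no branches, so FD = 0.
    """
    members = list(community)
    if len(members) == 0:
        return 0.0
    mask = np.zeros((1, model.n_species), dtype=bool)
    mask[0, model.index_of(members)] = True
    return float(fd_rows(mask, model)[0])


def fd_rows(presence: np.ndarray | pd.DataFrame, model: DendrogramModel) -> np.ndarray:
    """Vectorized FD for each row of a presence matrix (rows x pool species).

    An edge contributes when the community has members both below and outside
    it; the masked sum over edges runs as one matrix product.
    """
    if isinstance(presence, pd.DataFrame):
        cols = model.index_of(presence.columns)
        order = np.argsort(cols)
        arr = presence.to_numpy()[:, order] > 0
        if not np.array_equal(np.sort(cols), np.arange(model.n_species)):
            raise ValueError("presence matrix columns must cover the dendrogram pool exactly")
    else:
        arr = np.asarray(presence) > 0
        if arr.shape[1] != model.n_species:
            raise ValueError("presence matrix width must equal the pool size")
    richness = arr.sum(axis=1)
    below = arr.astype(float) @ model.edge_leaves.T.astype(float)  # (m, n_edges)
    included = (below > 0) & (below < richness[:, None])
    return included @ model.edge_lengths / model.total_branch_length


def null_ses(
    presence: pd.DataFrame,
    model: DendrogramModel,
    null: str = "frequency",
    n_iter: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """FD and standardized effect size per community against a richness-held null.

    For each community of richness S, ``n_iter`` random communities of S
    species are drawn from the pool without replacement — uniformly
    (``null="uniform"``) or with inclusion probability proportional to each
    species' observed occurrence frequency across point counts
    (``null="frequency"``, successive renormalized draws). SES is undefined
    (NaN, flagged) when the null FD has zero spread, e.g. when S equals the
    pool size.
    """
    if null not in ("uniform", "frequency"):
        raise ValueError("null must be 'uniform' or 'frequency'")
    rng = np.random.default_rng(seed)
    pool = model.n_species
    arr = presence.to_numpy() > 0
    if arr.shape[1] != pool:
        raise ValueError("presence matrix width must equal the pool size")
    richness = arr.sum(axis=1)
    if np.any(richness > pool):
        raise ValueError("community richness exceeds pool size")
    fd_obs = fd_rows(arr, model)

    if null == "frequency":
        freq = arr.sum(axis=0).astype(float)
        if freq.sum() == 0:
            freq = np.ones(pool)
        freq = np.maximum(freq, 1e-12)  # unrecorded species stay drawable in principle
        weights = freq / freq.sum()
    else:
        weights = np.full(pool, 1.0 / pool)

    null_mean = np.full(len(arr), np.nan)
    null_sd = np.full(len(arr), np.nan)
    for S in np.unique(richness):
        if S == 0:
            continue
        draws = _sample_without_replacement(rng, weights, int(S), n_iter)
        fd_null = fd_rows(draws, model)
        sel = richness == S
        null_mean[sel] = fd_null.mean()
        null_sd[sel] = fd_null.std(ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (fd_obs - null_mean) / null_sd
    ses = np.where((null_sd > 0) & np.isfinite(null_sd), ses, np.nan)
    return pd.DataFrame(
        {
            "point_id": presence.index,
            "richness": richness,
            "fd_obs": fd_obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "ses_flagged": ~np.isfinite(ses),
            "null_model": null,
            "n_iter": n_iter,
        }
    ).reset_index(drop=True)


def _sample_without_replacement(rng, weights: np.ndarray, size: int, n_draws: int) -> np.ndarray:
    """Weighted sampling without replacement, vectorized over draws.

    Uses exponential racing keys (equivalent in distribution to drawing
    species one at a time with renormalized probabilities).
    """
    pool = len(weights)
    if size > pool:
        raise ValueError("cannot draw more species than the pool holds")
    keys = rng.exponential(size=(n_draws, pool)) / weights
    chosen = np.argpartition(keys, size - 1, axis=1)[:, :size]
    out = np.zeros((n_draws, pool), dtype=bool)
    np.put_along_axis(out, chosen, True, axis=1)
    return out


def packing_correlation(fd_table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of SES with species richness across communities.

    A negative correlation means richer communities pack functionally similar
    species more tightly.
    """
    sel = fd_table.dropna(subset=["ses"])
    if len(sel) < 3:
        raise ValueError("need >= 3 finite SES values")
    if sel["ses"].nunique() == 1 or sel["richness"].nunique() == 1:
        raise ValueError("SES or richness is constant; correlation undefined")
    r, p = scipy.stats.pearsonr(sel["ses"], sel["richness"])
    return float(r), float(p)
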