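"""End-to-end orchestration: survey -> detectability -> densities -> selection
-> functional diversity -> inference, with a reproducibility manifest.

Stages communicate through plain CSV/JSON files when run via :func:`run_all`
(so each stage can be inspected and re-run independently); :func:`analyse`
performs the same computation in memory and is what the CLI, the tests and the
end-to-end recovery checks call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import detectability, functional_diversity as fdiv, inference, resource_selection
from .core_data import SurveyDataset, TraitTable, build_community_matrix, read_survey, validate


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    point_counts: str | None = None
    observations: str | None = None
    species: str | None = None
    quadrats: str | None = None
    traits: str | None = None
    out_dir: str = "guildfill_out"
    truncation_m: float = 100.0
    min_detections: int = 20
    availability_mode: str = "occupied"
    null_model: str = "frequency"
    n_iter: int = 1000
    moran_k: int = 8
    moran_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _group_density_per_point(dataset: SurveyDataset, densities: pd.DataFrame) -> pd.DataFrame:
    """Per point count: summed density of native and of non-native fitted species."""
    status = dataset.species.set_index("species_id")["status"]
    d = densities.copy()
    d["status"] = d["species_id"].map(status)
    wide = d.pivot_table(index="point_id", columns="status", values="density", aggfunc="sum")
    wide = wide.reindex(dataset.point_counts["point_id"]).fillna(0.0)
    for col in ("native", "nonnative"):
        if col not in wide:
            wide[col] = 0.0
    pc = dataset.point_counts.set_index("point_id")
    wide["rice"] = pc["habitat_class"].eq("rice").astype(int)
    wide["site_id"] = pc["site_id"]
    wide["x"] = pc["x"]
    wide["y"] = pc["y"]
    return wide.rename(columns={"native": "native_density", "nonnative": "nonnative_density"})


def _lrt_row(y, rice, site, response: str) -> dict[str, Any]:
    full = inference.fit_lmm(y, rice, site, response=response)
    reduced = inference.fit_lmm(y, None, site, response=response)
    res = inference.lrt(full, reduced)
    return {
        "response": response,
        "estimate": full.estimate,
        "se": full.se,
        "chi2": res.chi2,
        "df": res.df,
        "p": res.p,
        "flagged": full.flagged,
    }


def analyse(
    dataset: SurveyDataset,
    traits: TraitTable,
    config: RunConfig | None = None,
) -> dict[str, Any]:
    """Run the full analysis in memory.

    Returns a dict with the stage outputs: detection fits, densities, the
    detectability bias test, feeding/shelter selection tables and group
    comparisons, the FD/SES table with its dendrogram, habitat-model LRT rows
    and residual Moran's I checks.
    """
    config = config or RunConfig()
    out: dict[str, Any] = {}

    # detectability ---------------------------------------------------------
    try:
        fits, unmodelled = detectability.fit_all_species(
            dataset, w=config.truncation_m, min_detections=config.min_detections
        )
        if not fits:
            raise StageError("detectability: no species had enough detections to model")
        predictions = detectability.predict_p(dataset, fits)
        densities = detectability.estimate_density(dataset, fits)
        dataset.attach_densities(densities)
        out["detection_fits"] = fits
        out["unmodelled_species"] = unmodelled
        out["predictions"] = predictions
        out["densities"] = densities
        try:
            out["bias_test"] = detectability.detectability_bias_test(predictions, dataset)
        except ValueError as err:
            out["bias_test"] = None
            out["bias_test_note"] = str(err)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"detectability: {err}") from err

    # resource selection ----------------------------------------------------
    try:
        selection = pd.concat(
            [
                resource_selection.selection_table(dataset, act, mode=config.availability_mode)
                for act in ("feeding", "shelter")
            ],
            ignore_index=True,
        )
        out["selection"] = selection
        comparisons = []
        for act, res in (("shelter", "emergent"), ("shelter", "trees_bushes"),
                         ("feeding", "forbs"), ("feeding", "rough_grass")):
            try:
                wres = resource_selection.compare_selection(selection, dataset, res, act)
                comparisons.append(
                    {"activity": act, "resource": res, "W": wres.W, "p": wres.p,
                     "n_native": wres.n1, "n_nonnative": wres.n2}
                )
            except ValueError:
                continue
        out["selection_comparisons"] = pd.DataFrame(comparisons)
    except Exception as err:
        raise StageError(f"resource_selection: {err}") from err

    # functional diversity --------------------------------------------------
    try:
        if traits is None:
            raise StageError("functional_diversity: a trait table is required for this stage")
        D = fdiv.gower_distance(traits)
        model = fdiv.select_linkage(D)
        presence = build_community_matrix(dataset, "presence")
        presence = presence.reindex(columns=model.labels, fill_value=0)
        fd_table = fdiv.null_ses(
            presence, model, null=config.null_model, n_iter=config.n_iter, seed=config.seed
        )
        out["dendrogram"] = model
        out["fd"] = fd_table
        finite = fd_table.dropna(subset=["ses"])
        if len(finite) >= 3 and finite["ses"].nunique() > 1 and finite["richness"].nunique() > 1:
            out["packing_correlation"] = fdiv.packing_correlation(fd_table)
        # FD of the native-only community per point, for the habitat contrast
        status = dataset.species.set_index("species_id")["status"]
        native_cols = [s for s in model.labels if status.get(s) == "native"]
        native_presence = presence.copy()
        native_presence.loc[:, [c for c in presence.columns if c not in native_cols]] = 0
        out["fd_native"] = pd.Series(
            fdiv.fd_rows(native_presence, model), index=presence.index, name="fd_native"
        )
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"functional_diversity: {err}") from err

    # inference -------------------------------------------------------------
    try:
        grp = _group_density_per_point(dataset, densities)
        site = grp["site_id"].to_numpy()
        rice = grp["rice"].to_numpy()
        rows = [
            _lrt_row(grp["native_density"], rice, site, "native_density"),
            _lrt_row(grp["nonnative_density"], rice, site, "nonnative_density"),
        ]
        fd_all = out["fd"].set_index("point_id")["fd_obs"].reindex(grp.index)
        fd_nat = out["fd_native"].reindex(grp.index)
        rows.append(_lrt_row(fd_all.to_numpy(), rice, site, "fd_all"))
        rows.append(_lrt_row(fd_nat.to_numpy(), rice, site, "fd_native"))
        presence_bin = presence.reindex(grp.index)
        richness = presence_bin.sum(axis=1)
        rows.append(_lrt_row(richness.to_numpy(dtype=float), rice, site, "richness"))
        results = pd.DataFrame(rows)
        out["habitat_models"] = results

        coords = grp[["x", "y"]].to_numpy()
        moran_rows = []
        for response in ("native_density", "nonnative_density"):
            resid = _lmm_residuals(grp[response].to_numpy(dtype=float), rice, site)
            if np.ptp(resid) == 0:
                continue
            m = inference.morans_i(
                resid, coords, weights="knn", k=config.moran_k,
                n_perm=config.moran_permutations, seed=config.seed,
            )
            moran_rows.append({"response": response, "I": m.I, "expected": m.expected, "p": m.p})
        out["moran_residuals"] = pd.DataFrame(moran_rows)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"inference: {err}") from err

    # quadrats (optional) ---------------------------------------------------
    if dataset.quadrats is not None and len(dataset.quadrats):
        try:
            cwm = resource_selection.cwm_table(dataset.quadrats)
            out["cwm"] = cwm
            rice_cwm = cwm.loc[cwm["habitat"] == "rice_margin", "cwm_capacity_g"]
            other_cwm = cwm.loc[cwm["habitat"] != "rice_margin", "cwm_capacity_g"]
            if len(rice_cwm) and len(other_cwm):
                out["cwm_comparison"] = inference.wilcoxon_mw(other_cwm, rice_cwm)
        except Exception as err:
            raise StageError(f"quadrats: {err}") from err

    return out


def _lmm_residuals(y: np.ndarray, rice: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Residuals of the habitat fixed effect (rice-group demeaning).

    The site effect deliberately stays in the residual: it is exactly the
    structure the spatial diagnostic should be able to see.
    """
    resid = np.asarray(y, dtype=float).copy()
    for level in (0, 1):
        sel = rice == level
        if sel.any():
            resid[sel] -= resid[sel].mean()
    return resid


def headline_contrasts(result: dict[str, Any], dataset: SurveyDataset) -> dict[str, float]:
    """Signed headline effects used by end-to-end recovery checks.

    * ``nonnative_density_rice``: rice coefficient of the non-native density
      model (positive = denser in rice);
    * ``native_fd_rice``: rice coefficient of the native-community FD model
      (negative = natives less functionally diverse in rice);
    * ``emergent_shelter_gap``: mean non-native minus mean native Jacobs index
      for emergent vegetation as shelter (positive = non-natives prefer it more).
    """
    models = result["habitat_models"].set_index("response")
    sel = result["selection"]
    status = dataset.species.set_index("species_id")["status"]
    emergent = sel[(sel["activity"] == "shelter") & (sel["resource"] == "emergent")].dropna(subset=["J"])
    grp = emergent["species_id"].map(status)
    gap = (
        emergent.loc[grp.eq("nonnative"), "J"].mean() - emergent.loc[grp.eq("native"), "J"].mean()
        if grp.eq("nonnative").any() and grp.eq("native").any()
        else float("nan")
    )
    return {
        "nonnative_density_rice": float(models.loc["nonnative_density", "estimate"]),
        "native_fd_rice": float(models.loc["fd_native", "estimate"]),
        "emergent_shelter_gap": float(gap),
    }


def run_all(config: RunConfig) -> dict[str, Any]:
    """File-based pipeline run: read inputs, analyse, write CSVs + manifest.

    Deterministic given the config's seed; the manifest records the config,
    seeds and a sha256 checksum of every output file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not (config.point_counts and config.observations and config.species):
        raise StageError("import: point_counts, observations and species paths are required")
    try:
        dataset = read_survey(
            config.point_counts, config.observations, config.species,
            quadrat_path=config.quadrats, truncation_m=config.truncation_m,
        )
    except Exception as err:
        raise StageError(f"import: {err}") from err
    problems = validate(dataset)
    if problems:
        raise StageError(f"import: dataset invalid: {problems[:5]}")
    if config.traits is None:
        raise StageError("functional_diversity: config is missing the traits file")
    try:
        traits = TraitTable.from_csv(config.traits)
    except FileNotFoundError as err:
        raise StageError(f"functional_diversity: traits file not readable: {err}") from err

    result = analyse(dataset, traits, config)

    written: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    fits = result["detection_fits"]
    _write(
        "fits.csv",
        pd.DataFrame(
            {
                "species_id": list(fits),
                "terms": ["+".join(f.terms) for f in fits.values()],
                "beta": [json.dumps(list(np.round(f.beta, 6))) for f in fits.values()],
                "aic": [f.aic for f in fits.values()],
                "n_detections": [f.n_detections for f in fits.values()],
            }
        ),
    )
    _write("predictions.csv", result["predictions"])
    _write("densities.csv", result["densities"])
    _write("selection.csv", result["selection"])
    _write("selection_comparisons.csv", result["selection_comparisons"])
    _write("fd.csv", result["fd"])
    _write("habitat_models.csv", result["habitat_models"])
    _write("moran_residuals.csv", result["moran_residuals"])
    if "cwm" in result:
        _write("cwm.csv", result["cwm"])
    (out_dir / "dendrogram.nwk").write_text(result["dendrogram"].to_newick() + "\n")
    written["dendrogram.nwk"] = hashlib.sha256((out_dir / "dendrogram.nwk").read_bytes()).hexdigest()

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_point_counts": int(len(dataset.point_counts)),
        "n_observations": int(len(dataset.observations)),
        "n_rejected_distance": dataset.n_rejected_distance,
        "unmodelled_species": result["unmodelled_species"],
        "cophenetic_c": result["dendrogram"].cophenetic_c,
        "linkage": result["dendrogram"].linkage_method,
        "outputs": written,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
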