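"""Half-normal point-transect detection functions with covariates.

Detections of a species decline with distance r from the observer following a
half-normal curve g(r) = exp(-r^2 / 2 sigma^2). The scale sigma can depend on
covariates through log sigma = beta0 + beta' x; the covariates considered here
are the availability of emergent vegetation and of trees/bushes at the point
count (both can obscure birds) and the flock size (larger flocks are easier to
see; entered on the log scale).

Fitting uses the conditional (truncated) likelihood of the observed distances
within the truncation radius w,

    f(r | x) = g(r; sigma(x)) * r / integral_0^w g(s; sigma(x)) * s ds,

which is the standard point-transect likelihood under uniform-in-area
placement of birds. All 2^3 simplifications of the global covariate model are
fitted and the minimum-AIC model retained. Densities are obtained by dividing
the summed count at a point by the disc-averaged detection probability

    p = (2 sigma^2 / w^2) * (1 - exp(-w^2 / 2 sigma^2)).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .core_data import TRUNCATION_M, SurveyDataset

#: Detection covariates supported in the global model.
DETECTION_COVARIATES = ("emergent", "trees_bushes", "flock_size")

SIGMA_MIN = 0.5  # metres; fits pinned here are flagged as degenerate
SIGMA_MAX = 1e6


class FitError(RuntimeError):
    """The detection-function optimizer failed to converge."""


class InsufficientDataError(ValueError):
    """Too few detections to fit a detection model for this species."""


def halfnormal_p(sigma: float, w: float = TRUNCATION_M) -> float:
    """Disc-averaged detection probability under a half-normal detection curve.

    Averages g(r) = exp(-r^2/2sigma^2) over a uniform-in-area distribution of
    animals in the disc of radius ``w``:

        p = (2 sigma^2 / w^2) * (1 - exp(-w^2 / 2 sigma^2)).

    Strictly increasing in sigma; tends to 1 as sigma -> infinity and to
    2 sigma^2 / w^2 as sigma -> 0.
    """
    sigma = np.asarray(sigma, dtype=float)
    w = float(w)
    if np.any(sigma <= 0) or w <= 0:
        raise ValueError("sigma and w must be > 0")
    t = w**2 / (2.0 * sigma**2)
    out = -np.expm1(-t) / t
    return float(out) if out.ndim == 0 else out


def _design_matrix(obs: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Intercept + covariate columns on the log-sigma scale.

    Availability covariates are raw proportions in [0,1]; flock size enters as
    log(flock_size) since it is a skewed count.
    """
    cols = [np.ones(len(obs))]
    for term in terms:
        if term == "flock_size":
            cols.append(np.log(obs["flock_size"].to_numpy(dtype=float)))
        elif term in ("emergent", "trees_bushes"):
            cols.append(obs[f"avail_{term}"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown detection covariate {term!r}")
    return np.column_stack(cols)


@dataclasses.dataclass
class DetectionFit:
    """Fitted half-normal detection model for one species."""

    species_id: str
    terms: tuple[str, ...]  # covariates beyond the intercept
    beta: np.ndarray  # coefficients on log-sigma, intercept first
    w: float
    loglik: float
    aic: float
    n_detections: int
    converged: bool
    at_bound: bool = False

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def sigma(self, covariates: pd.DataFrame) -> np.ndarray:
        """Predicted sigma for rows carrying the model's covariate columns."""
        X = _design_matrix(covariates, self.terms)
        eta = np.clip(X @ self.beta, math.log(SIGMA_MIN), math.log(SIGMA_MAX))
        return np.exp(eta)

    def p(self, covariates: pd.DataFrame) -> np.ndarray:
        """Disc-averaged detection probability for each covariate row."""
        return halfnormal_p(self.sigma(covariates), self.w)


def _negloglik(beta: np.ndarray, X: np.ndarray, r: np.ndarray, w: float) -> float:
    eta = np.clip(X @ beta, math.log(SIGMA_MIN) - 1, math.log(SIGMA_MAX))
    sigma2 = np.exp(2.0 * eta)
    # log f(r) = log r - r^2/(2 sigma^2) - log(sigma^2 * (1 - exp(-w^2/2sigma^2)))
    t = w**2 / (2.0 * sigma2)
    log_norm = np.log(sigma2) + np.log(-np.expm1(-t))
    ll = np.log(np.maximum(r, 1e-9)) - r**2 / (2.0 * sigma2) - log_norm
    return -float(np.sum(ll))


def fit_halfnormal(
    observations: pd.DataFrame,
    terms: Sequence[str] = (),
    w: float = TRUNCATION_M,
    min_detections: int = 20,
    species_id: str | None = None,
) -> DetectionFit:
    """Maximum-likelihood half-normal fit for one species' detections.

    ``observations`` must carry ``distance_m`` plus the covariate columns the
    requested ``terms`` need (``avail_emergent``, ``avail_trees_bushes``,
    ``flock_size``).
    """
    n = len(observations)
    if n < min_detections:
        raise InsufficientDataError(
            f"{species_id or 'species'}: {n} detections < minimum {min_detections}"
        )
    r = observations["distance_m"].to_numpy(dtype=float)
    if np.any((r < 0) | (r > w)):
        raise ValueError("distances must lie in [0, w]")
    X = _design_matrix(observations, terms)
    k = X.shape[1]
    # start sigma at the rms of the distances (exact MLE for untruncated case)
    start = np.zeros(k)
    start[0] = math.log(max(np.sqrt(np.mean(r**2) / 2.0), SIGMA_MIN * 2))
    bounds = [(math.log(SIGMA_MIN), math.log(SIGMA_MAX))] + [(-20.0, 20.0)] * (k - 1)
    res = scipy.optimize.minimize(
        _negloglik, start, args=(X, r, w), method="L-BFGS-B", bounds=bounds,
    )
    if not res.success and abs(res.fun) > 1e12:
        raise FitError(f"{species_id or 'species'}: optimizer failed: {res.message}")
    beta = res.x
    loglik = -res.fun
    at_bound = bool(beta[0] <= math.log(SIGMA_MIN) + 1e-6 or beta[0] >= math.log(SIGMA_MAX) - 1e-6)
    return DetectionFit(
        species_id=species_id or "",
        terms=tuple(terms),
        beta=beta,
        w=w,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n_detections=n,
        converged=bool(res.success),
        at_bound=at_bound,
    )


def select_model(
    observations: pd.DataFrame,
    covariates: Sequence[str] = DETECTION_COVARIATES,
    w: float = TRUNCATION_M,
    min_detections: int = 20,
    species_id: str | None = None,
) -> DetectionFit:
    """Fit every simplification of the global covariate model, return min-AIC.

    All subsets of ``covariates`` (the intercept is always present) are fitted;
    AIC ties within 1e-6 are broken toward fewer parameters. Submodels whose
    optimizers fail are dropped; if every submodel fails a :class:`FitError`
    propagates.
    """
    fits: list[DetectionFit] = []
    last_err: Exception | None = None
    subsets = []
    for k in range(len(covariates) + 1):
        subsets.extend(itertools.combinations(covariates, k))
    for terms in subsets:
        try:
            fits.append(
                fit_halfnormal(observations, terms, w=w, min_detections=min_detections, species_id=species_id)
            )
        except InsufficientDataError:
            raise
        except (FitError, FloatingPointError) as err:  # pragma: no cover - rare
            last_err = err
    if not fits:
        raise FitError(f"{species_id or 'species'}: every candidate model failed") from last_err
    # minimum AIC; ties (< 1e-6) broken toward fewer parameters
    fits.sort(key=lambda f: (round(f.aic / 1e-6) * 1e-6, f.n_params))
    return fits[0]


def _observations_with_covariates(dataset: SurveyDataset) -> pd.DataFrame:
    pc = dataset.point_counts.set_index("point_id")
    obs = dataset.observations.copy()
    for col in ("avail_emergent", "avail_trees_bushes"):
        obs[col] = obs["point_id"].map(pc[col])
    return obs


def fit_all_species(
    dataset: SurveyDataset,
    covariates: Sequence[str] = DETECTION_COVARIATES,
    w: float = TRUNCATION_M,
    min_detections: int = 20,
) -> tuple[dict[str, DetectionFit], list[str]]:
    """AIC-selected detection fit per species with enough detections.

    Returns ``(fits, unmodelled)`` where ``unmodelled`` lists species recorded
    too infrequently (or whose fits all failed); those species are excluded
    from density analyses downstream.
    """
    obs = _observations_with_covariates(dataset)
    fits: dict[str, DetectionFit] = {}
    unmodelled: list[str] = []
    for species_id, group in obs.groupby("species_id", sort=False):
        try:
            fits[str(species_id)] = select_model(
                group, covariates=covariates, w=w, min_detections=min_detections, species_id=str(species_id)
            )
        except (InsufficientDataError, FitError):
            unmodelled.append(str(species_id))
    # species never observed at all are also unmodelled
    seen = set(obs["species_id"])
    for species_id in dataset.species["species_id"]:
        if species_id not in seen:
            unmodelled.append(str(species_id))
    return fits, unmodelled


def predict_p(
    dataset: SurveyDataset,
    fits: Mapping[str, DetectionFit],
) -> pd.DataFrame:
    """Detection probability of each fitted species at each point count.

    When flock size is in a species' selected model, the species' mean log
    flock size across its detections is used as the representative flock for
    point-level prediction (a point-level "typical flock").
    """
    rows = []
    pc = dataset.point_counts
    for species_id, fit in fits.items():
        cov = pd.DataFrame(
            {
                "avail_emergent": pc["avail_emergent"].to_numpy(),
                "avail_trees_bushes": pc["avail_trees_bushes"].to_numpy(),
            }
        )
        if "flock_size" in fit.terms:
            sizes = dataset.observations.loc[
                dataset.observations["species_id"] == species_id, "flock_size"
            ]
            rep = float(np.exp(np.mean(np.log(sizes)))) if len(sizes) else 1.0
            cov["flock_size"] = rep
        else:
            cov["flock_size"] = 1.0
        p = fit.p(cov)
        rows.append(
            pd.DataFrame({"point_id": pc["point_id"], "species_id": species_id, "p": p})
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["point_id", "species_id", "p"])
    return out


def estimate_density(
    dataset: SurveyDataset,
    fits: Mapping[str, DetectionFit],
    p_floor: float = 1e-3,
) -> pd.DataFrame:
    """Detectability-corrected density per point count and fitted species.

    Density = (sum of flock sizes counted at the point) / p(point), the
    detection probability predicted from the point's covariates. Species
    without a detection fit are omitted. Detection probabilities below
    ``p_floor`` are capped there (row flagged) to avoid exploding estimates.

    The returned table includes zero-count rows for every point x fitted
    species so downstream models see true zeros.
    """
    preds = predict_p(dataset, fits)
    counts = (
        dataset.observations.groupby(["point_id", "species_id"])["flock_size"]
        .sum()
        .rename("count")
        .reset_index()
    )
    out = preds.merge(counts, on=["point_id", "species_id"], how="left")
    out["count"] = out["count"].fillna(0).astype(float)
    capped = out["p"] < p_floor
    if capped.any():
        warnings.warn(f"{int(capped.sum())} detection probabilities below {p_floor}; capped")
    out["p_capped"] = capped
    out["density"] = out["count"] / out["p"].clip(lower=p_floor)
    return out


@dataclasses.dataclass
class BiasTestResult:
    """Native/non-native x rice interaction in predicted detectability."""

    estimate: float
    t: float
    p: float
    used_random_effect: bool
    note: str = ""


def detectability_bias_test(
    predictions: pd.DataFrame,
    dataset: SurveyDataset,
) -> BiasTestResult:
    """Test whether detectability differs between species groups and habitats.

    Models the predicted per-species, per-point detection probability as
    nonnative * rice with a site random intercept; the interaction term is the
    quantity of interest (a non-zero value means detectability bias differs
    between rice fields and other habitats by species origin, which could
    masquerade as a density difference). Falls back to an ordinary linear
    model when the random-intercept fit is singular or only one site exists.
    """
    import statsmodels.formula.api as smf

    pc = dataset.point_counts.set_index("point_id")
    status = dataset.species.set_index("species_id")["status"]
    df = predictions.copy()
    df["nonnative"] = df["species_id"].map(status).eq("nonnative").astype(float)
    df["rice"] = df["point_id"].map(pc["habitat_class"]).eq("rice").astype(float)
    df["site"] = df["point_id"].map(pc["site_id"])
    if df["nonnative"].nunique() < 2 or df["rice"].nunique() < 2:
        raise ValueError("need both species statuses and both habitat groups")

    formula = "p ~ nonnative * rice"
    if df["site"].nunique() >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, df, groups=df["site"]).fit(reml=False)
            term = "nonnative:rice"
            if np.isfinite(fit.bse[term]) and fit.bse[term] > 0:
                return BiasTestResult(
                    estimate=float(fit.params[term]),
                    t=float(fit.tvalues[term]),
                    p=float(fit.pvalues[term]),
                    used_random_effect=True,
                )
        except Exception:  # singular fits fall through to OLS
            pass
        note = "random-intercept fit singular; plain linear model used"
    else:
        note = "single site; plain linear model used"
    ols = smf.ols(formula, df).fit()
    term = "nonnative:rice"
    return BiasTestResult(
        estimate=float(ols.params[term]),
        t=float(ols.tvalues[term]),
        p=float(ols.pvalues[term]),
        used_random_effect=False,
        note=note,
    )
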