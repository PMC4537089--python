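"""Statistical engine: site-random-intercept models, LRTs, Moran's I, rank tests.

Point counts within a site are spatially clustered, so every regression in the
pipeline is a Gaussian mixed model with a site random intercept, fitted by
maximum likelihood (not REML) so that nested models can be compared with
likelihood-ratio tests. Residual spatial structure is checked with Moran's I
against a permutation null. Two-group species comparisons (native vs
non-native) use Wilcoxon-Mann-Whitney rank tests with the group-1 statistic
convention W = (rank sum of group 1) - n1(n1+1)/2, so 0 <= W <= n1*n2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.spatial
import scipy.stats


@dataclasses.dataclass
class MixedModelFit:
    """Gaussian random-intercept model fitted by ML."""

    response: str
    fixed_terms: tuple[str, ...]  # names of fixed effects beyond the intercept
    estimate: float  # coefficient of the first fixed term (0.0 if none)
    se: float
    group_var: float  # site random-intercept variance
    resid_var: float
    loglik: float
    n_obs: int
    n_fixed: int  # fixed-effect count incl. intercept
    converged: bool
    flagged: str = ""


def fit_lmm(
    y: np.ndarray | pd.Series,
    rice: np.ndarray | pd.Series | None,
    site: np.ndarray | pd.Series,
    response: str = "y",
) -> MixedModelFit:
    """Fit y ~ rice + (1 | site) by maximum likelihood.

    ``rice=None`` fits the intercept-only null model (same random structure),
    the reduced model of the habitat likelihood-ratio test. Constant responses
    and singular fits are returned flagged rather than raised.
    """
    import statsmodels.regression.mixed_linear_model as mlm

    y = np.asarray(y, dtype=float)
    site = np.asarray(site)
    if len(np.unique(site)) < 2:
        raise ValueError("need >= 2 sites for a site random intercept")
    if len(y) < 4:
        raise ValueError("need n >= 4 observations")
    terms: tuple[str, ...] = ()
    X = np.ones((len(y), 1))
    if rice is not None:
        rice = np.asarray(rice, dtype=float)
        X = np.column_stack([X, rice])
        terms = ("rice",)

    if np.ptp(y) == 0.0:
        return MixedModelFit(
            response=response, fixed_terms=terms, estimate=0.0, se=0.0,
            group_var=0.0, resid_var=0.0, loglik=np.nan, n_obs=len(y),
            n_fixed=X.shape[1], converged=False, flagged="constant response",
        )
    flagged = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mlm.MixedLM(y, X, groups=site)
        fit = model.fit(reml=False)
    if not getattr(fit, "converged", True):
        flagged = "not converged"
    idx = 1 if rice is not None else 0
    est = float(fit.fe_params[idx]) if rice is not None else 0.0
    se = float(fit.bse_fe[idx]) if rice is not None else 0.0
    group_var = float(np.squeeze(fit.cov_re))
    if group_var < 1e-10:
        flagged = (flagged + "; " if flagged else "") + "singular (site variance ~ 0)"
    return MixedModelFit(
        response=response, fixed_terms=terms, estimate=est, se=se,
        group_var=group_var, resid_var=float(fit.scale), loglik=float(fit.llf),
        n_obs=len(y), n_fixed=X.shape[1], converged=bool(getattr(fit, "converged", True)),
        flagged=flagged,
    )


@dataclasses.dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on the same data.

    chi2 = 2 (ll_full - ll_reduced), clamped at zero; df is the difference in
    fixed-effect count.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted to different data (n differs)")
    if not set(reduced.fixed_terms) <= set(full.fixed_terms) or reduced.n_fixed > full.n_fixed:
        raise ValueError("reduced model is not nested in the full model")
    if full.fixed_terms == reduced.fixed_terms:
        # degenerate comparison of a model with itself
        return LRTResult(chi2=0.0, df=0, p=1.0)
    df = full.n_fixed - reduced.n_fixed
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(chi2=chi2, df=df, p=float(scipy.stats.chi2.sf(chi2, df)))


@dataclasses.dataclass
class MoranResult:
    I: float
    expected: float  # -1/(n-1) under no autocorrelation
    p: float  # two-sided permutation p-value
    n: int
    weights: str


def _knn_weights(coords: np.ndarray, k: int) -> np.ndarray:
    n = len(coords)
    k = min(k, n - 1)
    tree = scipy.spatial.cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            W[i, j] = 1.0
    return W


def _inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    D = scipy.spatial.distance.cdist(coords, coords)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    if np.isinf(W).any():
        finite_max = W[np.isfinite(W)].max()
        warnings.warn("coincident points: inverse-distance weight capped at the finite maximum")
        W[np.isinf(W)] = finite_max
    return W


def morans_i(
    values: np.ndarray | pd.Series,
    coords: np.ndarray | None = None,
    weights: str | np.ndarray = "knn",
    k: int = 8,
    row_standardize: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.

    ``weights`` is "knn" (symmetrized k-nearest-neighbour, default k = 8),
    "inverse_distance", or an explicit n x n weight matrix (in which case
    ``coords`` is unused). Weight rows are row-standardized by default. The
    permutation p-value is two-sided about the null expectation -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("Moran's I is undefined for constant values")
    if isinstance(weights, str):
        if coords is None:
            raise ValueError("coords required unless an explicit weight matrix is given")
        coords = np.asarray(coords, dtype=float)
        if weights == "knn":
            W = _knn_weights(coords, k)
            W = np.maximum(W, W.T)  # symmetrize neighbourhoods
            wname = f"knn(k={k})"
        elif weights == "inverse_distance":
            W = _inverse_distance_weights(coords)
            wname = "inverse_distance"
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        W = np.asarray(weights, dtype=float)
        wname = "custom"
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
    S0 = W.sum()

    def stat(z: np.ndarray) -> float | np.ndarray:
        # z: (n,) or (m, n) centred values
        num = np.einsum("...i,ij,...j->...", z, W, z)
        den = np.einsum("...i,...i->...", z, z)
        return (n / S0) * num / den

    z = x - x.mean()
    I_obs = float(stat(z))
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    I_perm = stat(perms)
    p = (1.0 + np.sum(np.abs(I_perm - expected) >= np.abs(I_obs - expected) - 1e-12)) / (n_perm + 1.0)
    return MoranResult(I=I_obs, expected=expected, p=float(p), n=n, weights=wname)


@dataclasses.dataclass
class WilcoxonResult:
    W: float  # group-1 Mann-Whitney statistic, 0 <= W <= n1*n2
    p: float
    n1: int
    n2: int
    note: str = "W = rank sum of group 1 minus n1(n1+1)/2"


def wilcoxon_mw(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon-Mann-Whitney test, group-1 statistic convention.

    Exact p-value when n1*n2 <= 400 and there are no ties; otherwise the
    normal approximation with tie correction. A fully tied input returns
    W = n1*n2/2 with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return WilcoxonResult(W=n1 * n2 / 2.0, p=1.0, n1=n1, n2=n2,
                              note="all values tied; no rank information")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return WilcoxonResult(W=float(res.statistic), p=float(res.pvalue), n1=n1, n2=n2)


@dataclasses.dataclass
class InterceptTestResult:
    estimate: float
    t: float
    p: float
    method: str


def intercept_test(y, site=None) -> InterceptTestResult:
    """Test whether the mean of y differs from zero.

    With site identifiers, uses the intercept of a site-random-intercept mixed
    model (respecting within-site correlation); otherwise, or when the mixed
    fit is singular, falls back to a one-sample t test.
    """
    import statsmodels.regression.mixed_linear_model as mlm

    y = np.asarray(y, dtype=float)
    if site is not None and len(np.unique(np.asarray(site))) >= 2 and np.ptp(y) > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mlm.MixedLM(y, np.ones((len(y), 1)), groups=np.asarray(site)).fit(reml=False)
            se = float(fit.bse_fe[0])
            if np.isfinite(se) and se > 0:
                est = float(fit.fe_params[0])
                t = est / se
                return InterceptTestResult(
                    estimate=est, t=t, p=float(2 * scipy.stats.norm.sf(abs(t))),
                    method="mixed-model intercept",
                )
        except Exception:
            pass
    t, p = scipy.stats.ttest_1samp(y, 0.0)
    return InterceptTestResult(estimate=float(np.mean(y)), t=float(t), p=float(p), method="one-sample t")
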