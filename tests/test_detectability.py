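import numpy as np
import pandas as pd
import pytest
import scipy.integrate

from guildfill import detectability as det
from guildfill import synthetic
from guildfill.core_data import SurveyDataset

from conftest import make_observations, make_point_counts, make_species


def numeric_p(sigma, w=100.0):
    """Independent oracle: integrate g(r) against the radial density 2r/w^2."""
    val, _ = scipy.integrate.quad(
        lambda r: np.exp(-(r**2) / (2 * sigma**2)) * 2 * r / w**2, 0.0, w
    )
    return val


def sample_distances(rng, sigma, w, n):
    """Inverse-CDF draws from the truncated half-normal point-transect density."""
    u = rng.random(n)
    cmax = -np.expm1(-(w**2) / (2 * sigma**2))
    return sigma * np.sqrt(-2.0 * np.log1p(-u * cmax))


@pytest.mark.parametrize("sigma", [1.0, 5.0, 10.0, 40.0, 100.0, 1e3, 1e5])
def test_halfnormal_p_matches_numerical_integration(sigma):
    assert det.halfnormal_p(sigma, 100.0) == pytest.approx(numeric_p(sigma), abs=1e-8)


def test_halfnormal_p_limits_and_monotonicity():
    assert det.halfnormal_p(1e6, 100.0) == pytest.approx(1.0, abs=1e-6)
    # small-sigma limit: p -> 2 sigma^2 / w^2
    assert det.halfnormal_p(10.0, 100.0) == pytest.approx(0.02, rel=1e-3)
    sigmas = np.logspace(0, 5, 60)
    ps = np.array([det.halfnormal_p(s, 100.0) for s in sigmas])
    assert np.all(np.diff(ps) > 0)
    with pytest.raises(ValueError):
        det.halfnormal_p(0.0, 100.0)
    with pytest.raises(ValueError):
        det.halfnormal_p(10.0, -1.0)


def test_sigma_recovery_without_covariates():
    rng = np.random.default_rng(10)
    r = sample_distances(rng, 40.0, 100.0, 500)
    obs = pd.DataFrame({"distance_m": r, "flock_size": 1})
    fit = det.fit_halfnormal(obs, (), species_id="sim")
    sigma_hat = float(np.exp(fit.beta[0]))
    assert abs(sigma_hat - 40.0) / 40.0 < 0.10
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)


def test_likelihood_peaks_near_truth():
    """The conditional likelihood at the MLE beats perturbed sigma values."""
    rng = np.random.default_rng(11)
    r = sample_distances(rng, 40.0, 100.0, 400)
    obs = pd.DataFrame({"distance_m": r, "flock_size": 1})
    fit = det.fit_halfnormal(obs, ())
    X = np.ones((len(r), 1))
    for factor in (0.7, 1.4):
        perturbed = -det._negloglik(fit.beta + np.log(factor), X, r, 100.0)
        assert fit.loglik > perturbed


def test_degenerate_zero_distances_pin_sigma_at_bound():
    obs = pd.DataFrame({"distance_m": np.zeros(30), "flock_size": 1})
    fit = det.fit_halfnormal(obs, ())
    assert fit.at_bound
    assert np.exp(fit.beta[0]) == pytest.approx(det.SIGMA_MIN, rel=1e-3)


def test_too_few_detections_raises():
    obs = pd.DataFrame({"distance_m": [10.0, 20.0], "flock_size": 1})
    with pytest.raises(det.InsufficientDataError):
        det.fit_halfnormal(obs, (), min_detections=20)


def _simulate_covariate_data(rng, n, beta_em):
    avail = rng.uniform(0, 1, n)
    sigma = 40.0 * np.exp(beta_em * avail)
    r = np.array([sample_distances(rng, s, 100.0, 1)[0] for s in sigma])
    return pd.DataFrame({"distance_m": r, "avail_emergent": avail, "flock_size": 1})


def test_model_selection_null_covariate_prefers_intercept():
    """With no true effect, AIC keeps the intercept-only model most of the time.

    (A 1-df nuisance term wins AIC with probability P(chi2_1 > 2) ~ 0.16, so
    the long-run intercept-preference rate is ~84%; 40 seeded replicates.)
    """
    rng = np.random.default_rng(12)
    wins = 0
    reps = 40
    for _ in range(reps):
        obs = _simulate_covariate_data(rng, 500, beta_em=0.0)
        fit = det.select_model(obs, covariates=("emergent",))
        if fit.terms == ():
            wins += 1
        else:
            assert abs(fit.beta[1]) < 0.5
    assert wins >= 0.8 * reps


def test_model_selection_finds_strong_covariate():
    rng = np.random.default_rng(13)
    hits = 0
    reps = 20
    for _ in range(reps):
        obs = _simulate_covariate_data(rng, 500, beta_em=-1.0)
        fit = det.select_model(obs, covariates=("emergent",))
        if "emergent" in fit.terms:
            hits += 1
    assert hits >= 0.8 * reps


def test_aic_tie_prefers_fewer_parameters():
    fits = [
        det.DetectionFit("x", ("emergent",), np.array([3.0, 0.0]), 100, -10.0, 24.0, 50, True),
        det.DetectionFit("x", (), np.array([3.0]), 100, -11.0, 24.0, 50, True),
    ]
    fits.sort(key=lambda f: (round(f.aic / 1e-6) * 1e-6, f.n_params))
    assert fits[0].terms == ()


def test_density_definition_and_zero_count():
    pc = make_point_counts([("S1", "P1", "rice", {}), ("S1", "P2", "rice", {})])
    obs = make_observations(
        [("P1", "A", 10.0, 7, "feeding", "forbs"), ("P1", "A", 20.0, 3, "feeding", "forbs")]
    )
    ds = SurveyDataset(species=make_species(["A"]), point_counts=pc, observations=obs)
    # a fit with a huge fixed sigma: p == 1 everywhere
    fit = det.DetectionFit("A", (), np.array([np.log(1e6)]), 100.0, 0.0, 2.0, 2, True)
    dens = det.estimate_density(ds, {"A": fit}).set_index("point_id")
    assert dens.loc["P1", "count"] == 10  # sum of flock sizes
    assert dens.loc["P1", "density"] == pytest.approx(10.0 / det.halfnormal_p(1e6, 100.0))
    assert dens.loc["P2", "count"] == 0 and dens.loc["P2", "density"] == 0.0
    # density = count / p exactly
    fit2 = det.DetectionFit("A", (), np.array([np.log(50.0)]), 100.0, 0.0, 2.0, 2, True)
    dens2 = det.estimate_density(ds, {"A": fit2}).set_index("point_id")
    p = det.halfnormal_p(50.0, 100.0)
    assert dens2.loc["P1", "density"] == pytest.approx(10.0 / p)
    assert dens2.loc["P1", "density"] >= dens2.loc["P1", "count"]


def test_density_recovery_is_unbiased():
    """Mean(estimated density - true abundance) ~ 0 over >= 200 simulated points."""
    cfg = synthetic.ScenarioConfig(
        species=[
            synthetic.SpeciesConfig(
                species_id="X", status="native", body_mass_g=20.0,
                lambda_rice=3.0, lambda_other=3.0, sigma0=45.0, mean_flock=2.0,
            )
        ],
        n_rice_sites=20, n_other_sites=5, site_effect_sd=0.0,
        points_mean=10, points_sd=0.0, points_range=(10, 10),
    )
    dataset, truth = synthetic.generate_survey(cfg, seed=14)
    assert len(dataset.point_counts) >= 200
    fits, _ = det.fit_all_species(dataset, covariates=("flock_size",), min_detections=20)
    dens = det.estimate_density(dataset, fits)
    merged = dens.merge(truth.true_abundance, on=["point_id", "species_id"])
    err = merged["density"] - merged["abundance"]
    se = err.std(ddof=1) / np.sqrt(len(err))
    assert abs(err.mean()) < 3 * se


def _bias_test_dataset(native_rice_p_boost):
    """Synthetic predictions: native species detectability raised in rice only."""
    rng = np.random.default_rng(15)
    pc = make_point_counts(
        [(f"S{i // 4 + 1}", f"P{i + 1}", "rice" if i % 2 == 0 else "wetland", {}) for i in range(80)]
    )
    sp = make_species(["n1", "n2", "x1", "x2"], ["native", "native", "nonnative", "nonnative"])
    ds = SurveyDataset(species=sp, point_counts=pc, observations=make_observations([]))
    rows = []
    for _, p in pc.iterrows():
        for s in sp["species_id"]:
            base = 0.5 + rng.normal(0, 0.02)
            if s.startswith("n") and p["habitat_class"] == "rice":
                base += native_rice_p_boost
            rows.append({"point_id": p["point_id"], "species_id": s, "p": base})
    return ds, pd.DataFrame(rows)


def test_bias_test_detects_native_advantage_in_rice():
    """Native detectability raised only in rice -> negative nonnative x rice term.

    (The interaction is coded on a non-native indicator, so a native-only
    boost in rice appears with a negative sign.)
    """
    ds, preds = _bias_test_dataset(0.2)
    res = det.detectability_bias_test(preds, ds)
    assert res.estimate < 0
    assert abs(res.t) > 2


def test_bias_test_null_is_quiet():
    ds, preds = _bias_test_dataset(0.0)
    res = det.detectability_bias_test(preds, ds)
    assert abs(res.t) < 2


def test_bias_test_single_site_falls_back_to_ols():
    ds, preds = _bias_test_dataset(0.2)
    ds.point_counts["site_id"] = "S1"
    res = det.detectability_bias_test(preds, ds)
    assert not res.used_random_effect
    assert "single site" in res.note
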