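"""Bayesian machinery: HDIs, R-hat, Savage-Dickey, conjugacy, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samloc.infer import (
    DiscriminationResult,
    LocalizationModelSpec,
    Posterior,
    bf10_from_samples,
    classify_bf,
    discrimination_bf10_bruteforce,
    fit_discrimination,
    fit_discrimination_mcmc,
    fit_localization,
    fit_single_predictor,
    gelman_rubin,
    hdi,
    pool_posteriors,
    savage_dickey_bf,
)
from samloc.simulate import predict_weighted_average


# ---------------------------------------------------------------------- HDI


def test_hdi_symmetric_matches_central_interval():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 100_000)
    lo, hi = hdi(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hdi_beta_matches_density_grid_oracle():
    """HDI of Beta(2, 8) samples vs the highest-density region found by
    thresholding the analytic density on a fine grid."""
    rng = np.random.default_rng(1)
    x = rng.beta(2, 8, 200_000)
    lo, hi = hdi(x, 0.95)
    grid = np.linspace(0, 1, 20_001)
    pdf = stats.beta(2, 8).pdf(grid)
    order = np.argsort(pdf)[::-1]
    cdf_mass = np.cumsum(pdf[order]) / pdf.sum()
    region = np.sort(grid[order[: np.searchsorted(cdf_mass, 0.95) + 1]])
    assert lo == pytest.approx(region[0], abs=0.01)
    assert hi == pytest.approx(region[-1], abs=0.01)


def test_hdi_mass_one_and_errors():
    x = np.arange(100.0)
    assert hdi(x, 1.0) == (0.0, 99.0)
    with pytest.raises(ValueError):
        hdi(x, 0.0)
    with pytest.raises(ValueError):
        hdi(x, 1.5)
    with pytest.raises(ValueError):
        hdi(np.array([1.0]))


def test_hdi_contains_requested_mass():
    rng = np.random.default_rng(2)
    x = rng.gamma(3, 2, 50_000)
    lo, hi = hdi(x, 0.9)
    frac = np.mean((x >= lo) & (x <= hi))
    assert 0.899 <= frac <= 0.92


# ------------------------------------------------------------------- R-hat


def test_gelman_rubin_identical_chains():
    chain = np.random.default_rng(3).normal(size=5000)
    assert gelman_rubin(np.vstack([chain, chain, chain])) == pytest.approx(1.0, abs=1e-3)


def test_gelman_rubin_detects_nonconvergence():
    rng = np.random.default_rng(4)
    chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
    assert gelman_rubin(chains) > 5.0


def test_gelman_rubin_iid_chains_near_one():
    rng = np.random.default_rng(5)
    assert gelman_rubin(rng.normal(size=(3, 5000))) < 1.01


def test_gelman_rubin_single_chain_raises():
    with pytest.raises(ValueError):
        gelman_rubin(np.zeros((1, 100)))


# ----------------------------------------------------------- Savage-Dickey


def test_savage_dickey_trivial_and_errors():
    assert savage_dickey_bf(1.0, 1.0) == 1.0  # posterior == prior
    assert savage_dickey_bf(0.25, 1.0) == 4.0
    with pytest.raises(ValueError):
        savage_dickey_bf(0.5, 0.0)


@pytest.mark.parametrize(
    "bf,label",
    [(0.5, "anecdotal"), (5.0, "substantial"), (15.0, "strong"),
     (50.0, "very strong"), (500.0, "decisive")],
)
def test_bf_classification_scale(bf, label):
    assert classify_bf(bf) == label


def test_savage_dickey_beta_case_two_oracles():
    """Beta(1,1) prior -> Beta(11,11) posterior at 0.5: the Savage-Dickey
    ratio equals 1/pdf and matches marginal-likelihood integration (K=10,
    N=20 produces exactly this posterior)."""
    analytic = savage_dickey_bf(stats.beta(11, 11).pdf(0.5), 1.0)
    assert analytic == pytest.approx(1.0 / stats.beta(11, 11).pdf(0.5), rel=1e-12)
    assert analytic == pytest.approx(discrimination_bf10_bruteforce(10, 20), rel=1e-9)


def test_bf10_from_samples_kde_matches_analytic():
    rng = np.random.default_rng(6)
    samples = rng.beta(11, 11, 100_000)
    kde_bf = bf10_from_samples(samples, 0.5, 1.0)
    exact = 1.0 / stats.beta(11, 11).pdf(0.5)
    assert kde_bf == pytest.approx(exact, rel=0.1)


# ----------------------------------------------------------- discrimination


def test_fit_discrimination_degenerate_and_conjugate_mean():
    res0 = fit_discrimination(0, 0)
    assert res0.bf10 == pytest.approx(1.0)
    assert res0.theta_mean == 0.5
    res = fit_discrimination(20, 20)
    assert res.theta_mean == pytest.approx(21 / 22)
    assert res.excludes_null
    with pytest.raises(ValueError):
        fit_discrimination(5, 3)


def test_fit_discrimination_bf_against_bruteforce():
    for k, n in [(30, 160), (0, 7), (7, 7), (50, 100), (199, 200)]:
        res = fit_discrimination(k, n)
        assert res.bf10 == pytest.approx(discrimination_bf10_bruteforce(k, n), rel=1e-6)


def test_discrimination_mcmc_conjugacy():
    """The MCMC theta posterior must match Beta(K+1, N-K+1) moments within
    3 Monte-Carlo standard errors (effective sample size via autocorrelation)."""
    import arviz as az

    k, n = 30, 160
    post = fit_discrimination_mcmc(k, n, seed=0)
    chains = post.samples["theta"]
    ess = float(az.ess(az.convert_to_inference_data(chains))["x"])
    exact = stats.beta(k + 1, n - k + 1)
    se_mean = exact.std() / np.sqrt(ess)
    assert chains.mean() == pytest.approx(exact.mean(), abs=3 * se_mean)
    assert chains.std(ddof=1) == pytest.approx(exact.std(), rel=0.1)


def test_discrimination_mcmc_prior_recovery():
    """With zero data the sampler must return the uniform prior
    (Kolmogorov-Smirnov at alpha = 0.01)."""
    post = fit_discrimination_mcmc(0, 0, seed=1)
    x = post.pooled("theta")[::15]  # thin to de-correlate
    assert stats.kstest(x, "uniform").pvalue > 0.01


# ------------------------------------------------------------- localization


def test_fit_localization_recovers_known_parameters(one_cell_data):
    singles, doubles, truth = one_cell_data
    post = fit_localization(singles, doubles, n_chains=3, n_samples=4000, n_burn=2000, seed=0)
    assert post.mean("w[0,120]") == pytest.approx(truth["w"], abs=0.1)
    assert post.mean("g") == pytest.approx(truth["g"], abs=0.1)
    assert post.mean("b") == pytest.approx(truth["b"], abs=3.0)
    assert post.mean("sigma_d[0,120]") == pytest.approx(truth["sigma_d"], rel=0.3)
    assert post.max_rhat() < 1.1


def test_fit_localization_w_fixed_at_one(one_cell_data):
    """When the generator ignores the distractor (w = 1) the weight posterior
    concentrates near 1."""
    singles, doubles, _ = one_cell_data
    rng = np.random.default_rng(7)
    d = doubles.copy()
    d["response_el"] = rng.normal(d.target_el, 10.0)
    post = fit_localization(singles, d, n_chains=3, n_samples=4000, n_burn=2000, seed=1)
    assert post.mean("w[0,120]") > 0.9


def test_fit_localization_unidentifiable_w_returns_prior(one_cell_data):
    """With target == distractor the likelihood is independent of w, so its
    marginal posterior is the uniform Beta(1,1) prior."""
    singles, doubles, _ = one_cell_data
    rng = np.random.default_rng(8)
    d = doubles.copy()
    d["distractor_el"] = d["target_el"]
    d["response_el"] = rng.normal(d.target_el, 10.0)
    post = fit_localization(singles, d, n_chains=3, n_samples=6000, n_burn=3000, seed=2)
    w = post.pooled("w[0,120]")
    assert w.mean() == pytest.approx(0.5, abs=0.06)
    assert w.std(ddof=1) == pytest.approx(np.sqrt(1 / 12), abs=0.04)


def test_fit_localization_validation(one_cell_data):
    singles, doubles, _ = one_cell_data
    with pytest.raises(ValueError):
        fit_localization(singles.iloc[:0], doubles)
    bad = doubles.copy()
    bad.loc[bad.index[0], "response_el"] = np.nan
    with pytest.raises(ValueError):
        fit_localization(singles, bad)


def test_prior_sensitivity_of_weight(one_cell_data):
    """Halving/doubling the Gamma prior's shape and rate moves the weight
    posterior mean by < 0.02 at experiment-scale n."""
    singles, doubles, _ = one_cell_data
    means = []
    for shape, rate in [(1.0, 0.04), (0.5, 0.02), (2.0, 0.08)]:
        spec = LocalizationModelSpec(prior_sigma_shape=shape, prior_sigma_rate=rate)
        post = fit_localization(
            singles, doubles, spec=spec, n_chains=3, n_samples=4000, n_burn=2000, seed=3
        )
        means.append(post.mean("w[0,120]"))
    assert max(means) - min(means) < 0.02


# --------------------------------------------------------- single predictor


def test_single_predictor_perfect_line():
    x = np.linspace(-45, 75, 40)
    post = fit_single_predictor(x, x, seed=0)
    assert post.mean("g") == pytest.approx(1.0, abs=0.02)
    assert post.mean("b") == pytest.approx(0.0, abs=1.0)


def test_single_predictor_shuffled_pairs_destroys_gain():
    rng = np.random.default_rng(9)
    x = np.tile(np.linspace(-45, 75, 25), 4)
    y = 0.9 * x + rng.normal(0, 8, x.size)
    post = fit_single_predictor(x, rng.permutation(y), seed=1)
    lo, hi = post.hdi("g")
    assert lo < 0.0 < hi or abs(post.mean("g")) < 0.15


def test_single_predictor_needs_three_points():
    with pytest.raises(ValueError):
        fit_single_predictor([0.0, 1.0], [0.0, 1.0])


def test_wa_predictor_regression_recovers_unit_gain(one_cell_data):
    """Regressing WA-generated responses on the WA prediction itself yields
    gain ~1 — the model-comparison logic behind the bottom-row fits."""
    _, doubles, truth = one_cell_data
    pred = predict_weighted_average(
        doubles.target_el, doubles.distractor_el, truth["w"], truth["g"], truth["b"]
    )
    post = fit_single_predictor(pred, doubles.response_el.to_numpy(), seed=2)
    assert post.mean("g") == pytest.approx(1.0, abs=0.15)


# ----------------------------------------------------------------- pooling


def _toy_posterior(mean, n=2000, seed=0, n_chains=2):
    rng = np.random.default_rng(seed)
    return Posterior({"w[0,120]": rng.normal(mean, 0.05, (n_chains, n))},
                     conditions=[(0.0, 120.0)])


def test_pool_single_posterior_identity():
    p = _toy_posterior(0.4)
    assert pool_posteriors([p]) is p


def test_pool_disjoint_posteriors_widens_hdi():
    a = _toy_posterior(0.2, seed=1)
    b = _toy_posterior(0.8, seed=2)
    pooled = pool_posteriors([a, b])
    lo, hi = pooled.hdi("w[0,120]")
    assert lo < 0.3 and hi > 0.7
    assert pooled.mean("w[0,120]") == pytest.approx(
        (a.mean("w[0,120]") + b.mean("w[0,120]")) / 2, abs=1e-9
    )


def test_pool_mismatched_names_raises():
    a = _toy_posterior(0.2)
    b = Posterior({"other": np.zeros((2, 10))})
    with pytest.raises(ValueError):
        pool_posteriors([a, b])


def test_model_contrast_bistable_inflates_sigma_d(one_cell_data):
    """Fitting the WA model to bistable data yields a larger posterior
    sigma_d than fitting it to WA data with the same generator SD."""
    singles, doubles, truth = one_cell_data
    rng = np.random.default_rng(10)
    bi = doubles.copy()
    pick = rng.random(len(bi)) < 0.5
    mu = np.where(pick, bi.target_el, bi.distractor_el)
    bi["response_el"] = rng.normal(mu, truth["sigma_d"])
    post_wa = fit_localization(singles, doubles, n_chains=2, n_samples=3000, n_burn=1500, seed=4)
    post_bi = fit_localization(singles, bi, n_chains=2, n_samples=3000, n_burn=1500, seed=4)
    assert post_bi.mean("sigma_d[0,120]") > post_wa.mean("sigma_d[0,120]")
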