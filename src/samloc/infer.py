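"""Bayesian estimation of the localization and discrimination models.

Localization (joint model, one listener): single-sound responses follow
``R ~ Normal(g*T + b, sigma_s)`` and double-sound responses follow the
weighted-average model ``R ~ Normal(g*(w*T + (1-w)*D) + b, sigma_d)``, with
the gain ``g``, bias ``b`` and single-sound SD shared across all interleaved
trials and a separate weight ``w`` and double-sound SD per (level
difference, modulation frequency) condition.  Priors: b ~ Normal(0, 10) deg,
g ~ Normal(1, 10), sigma ~ Gamma (essentially flat over plausible values),
w ~ Beta(1, 1).

Sampling is adaptive random-walk Metropolis-within-Gibbs: scalar updates for
(g, b, sigma_s) and blocked vector updates across conditions for the
``w``/``sigma_d`` sets (conditionally independent given the shared
parameters).  Step sizes adapt toward ~38% acceptance during burn-in only,
so the kept chain is a valid Markov chain.  Convergence is monitored with
the Gelman-Rubin potential scale reduction factor; credible intervals are
95% highest-density intervals; nested point hypotheses are tested with
Savage-Dickey density-ratio Bayes factors.

The 2AFC discrimination model ``K ~ Binomial(theta, N)`` with a uniform
Beta(1, 1) prior is conjugate — the posterior is Beta(K+1, N-K+1) exactly —
and an MCMC path is provided for cross-checking the samplers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import TrialTable

__all__ = [
    "LocalizationModelSpec",
    "Posterior",
    "DiscriminationResult",
    "hdi",
    "gelman_rubin",
    "savage_dickey_bf",
    "classify_bf",
    "bf10_from_samples",
    "fit_localization",
    "fit_single_predictor",
    "fit_discrimination",
    "fit_discrimination_mcmc",
    "pool_posteriors",
    "join_responses",
]

_TARGET_ACCEPT = 0.38
_ADAPT_EVERY = 50


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalizationModelSpec:
    """Priors for the joint localization model.

    The bias and gain priors correspond to the normal-hearing population
    (bias centred at 0 deg, gain at 1, both essentially flat with SD 10).
    The Gamma prior on each SD defaults to shape 1, rate 0.04 (mean 25 deg,
    effectively flat over 0-50 deg); the weight prior is uniform Beta(1, 1).
    """

    prior_b_mean: float = 0.0
    prior_b_sd: float = 10.0
    prior_g_mean: float = 1.0
    prior_g_sd: float = 10.0
    prior_sigma_shape: float = 1.0
    prior_sigma_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.prior_b_sd <= 0 or self.prior_g_sd <= 0:
            raise ValueError("prior SDs must be positive")
        if self.prior_sigma_shape <= 0 or self.prior_sigma_rate <= 0:
            raise ValueError("Gamma prior parameters must be positive")

    def logp_sigma(self, sigma: np.ndarray | float):
        return (self.prior_sigma_shape - 1.0) * np.log(sigma) - self.prior_sigma_rate * sigma


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples for an HDI")
    if mass == 1.0:
        return float(x[0]), float(x[-1])
    k = int(math.ceil(mass * n))
    k = max(2, min(k, n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_samples).  R-hat compares the pooled
    (between + within) variance estimate to the mean within-chain variance;
    values near 1 indicate convergence (< 1.1 is the usual criterion).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    # (m+1)/m sampling-variability correction of Brooks & Gelman
    return float(np.sqrt((m + 1) / m * var_plus / w - (n - 1) / (m * n)))


@dataclass
class Posterior:
    """MCMC output: parameter name -> (n_chains, n_kept) sample array."""

    samples: dict[str, np.ndarray]
    seed: int | None = None
    n_burn: int = 0
    conditions: list[tuple[float, float]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.samples)

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def pooled(self, name: str) -> np.ndarray:
        return self.samples[name].ravel()

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def sd(self, name: str) -> float:
        return float(self.pooled(name).std(ddof=1))

    def hdi(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hdi(self.pooled(name), mass)

    def rhat(self, name: str) -> float:
        return gelman_rubin(self.samples[name])

    def max_rhat(self) -> float:
        return max(self.rhat(k) for k in self.names)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        multi = self.n_chains >= 2
        for name in self.names:
            lo, hi = self.hdi(name, mass)
            rows.append(
                dict(
                    parameter=name,
                    mean=self.mean(name),
                    sd=self.sd(name),
                    hdi_lo=lo,
                    hdi_hi=hi,
                    rhat=self.rhat(name) if multi else np.nan,
                )
            )
        return pd.DataFrame(rows)


def pool_posteriors(posteriors: list[Posterior]) -> Posterior:
    """Pool posterior samples across subjects (concatenation, not hierarchy).

    Group summaries (means, HDIs) are computed on the pooled samples.  All
    posteriors must expose the same parameter names.
    """
    if not posteriors:
        raise ValueError("nothing to pool")
    names = posteriors[0].names
    for p in posteriors[1:]:
        if p.names != names:
            raise ValueError("posteriors have mismatched parameter names")
    if len(posteriors) == 1:
        return posteriors[0]
    pooled: dict[str, np.ndarray] = {}
    for name in names:
        arrs = [p.samples[name] for p in posteriors]
        widths = {a.shape[1] for a in arrs}
        if len(widths) == 1:
            pooled[name] = np.vstack(arrs)
        else:  # unequal lengths: pool into a single chain
            pooled[name] = np.concatenate([a.ravel() for a in arrs])[None, :]
    return Posterior(pooled, conditions=posteriors[0].conditions)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def savage_dickey_bf(
    posterior_density_at_point: float, prior_density_at_point: float
) -> float:
    """Savage-Dickey Bayes factor BF10 for a nested point hypothesis.

    BF10 = prior density / posterior density, both evaluated at the null
    value.  BF10 > 1 favours the alternative (density moved away from the
    null); BF10 < 1 favours the null.
    """
    if prior_density_at_point <= 0:
        raise ValueError("prior density at the null point must be positive "
                         "(the null must be nested in the alternative)")
    if posterior_density_at_point < 0:
        raise ValueError("densities must be nonnegative")
    if posterior_density_at_point == 0:
        return np.inf
    return prior_density_at_point / posterior_density_at_point


def classify_bf(bf10: float) -> str:
    """Evidence label on the conventional 3/10/30/100 scale."""
    if bf10 > 100:
        return "decisive"
    if bf10 > 30:
        return "very strong"
    if bf10 > 10:
        return "strong"
    if bf10 > 3:
        return "substantial"
    return "anecdotal"


def bf10_from_samples(
    samples: np.ndarray, point: float, prior_density_at_point: float
) -> float:
    """Savage-Dickey BF10 with the posterior density estimated by Gaussian
    KDE (Silverman bandwidth) at the null point.

    For the conjugate Beta case prefer :func:`fit_discrimination`, whose
    analytic density this estimator is validated against.
    """
    kde = stats.gaussian_kde(np.asarray(samples, dtype=float).ravel())
    return savage_dickey_bf(float(kde(point)[0]), prior_density_at_point)


# ---------------------------------------------------------------------------
# discrimination model (conjugate + MCMC cross-check)
# ---------------------------------------------------------------------------


@dataclass
class DiscriminationResult:
    """Exact conjugate inference for the 2AFC identification rate theta."""

    k: int
    n: int
    theta_mean: float
    hdi_95: tuple[float, float]
    bf10: float
    evidence: str
    posterior: stats._distn_infrastructure.rv_continuous_frozen

    @property
    def excludes_null(self) -> bool:
        lo, hi = self.hdi_95
        return not (lo <= 0.5 <= hi)


def _beta_hdi(a: float, b: float, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval of a Beta(a, b) by minimizing ppf(p+mass)-ppf(p)."""
    dist = stats.beta(a, b)
    if mass >= 1.0:
        return 0.0, 1.0
    res = optimize.minimize_scalar(
        lambda p: dist.ppf(p + mass) - dist.ppf(p),
        bounds=(0.0, 1.0 - mass),
        method="bounded",
        options={"xatol": 1e-10},
    )
    p = float(res.x)
    # the optimum may sit exactly at a boundary (monotone densities)
    cands = [p, 0.0, 1.0 - mass]
    p = min(cands, key=lambda q: dist.ppf(q + mass) - dist.ppf(q))
    return float(dist.ppf(p)), float(dist.ppf(p + mass))


def fit_discrimination(k: int, n: int) -> DiscriminationResult:
    """Posterior for theta given K correct out of N: Beta(K+1, N-K+1).

    The Savage-Dickey BF10 against H0: theta = 0.5 is the uniform prior
    density (1) over the posterior density at 0.5.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= K <= N")
    a, b = k + 1.0, n - k + 1.0
    post = stats.beta(a, b)
    dens0 = float(post.pdf(0.5))
    bf10 = np.inf if dens0 == 0 else 1.0 / dens0
    return DiscriminationResult(
        k=k,
        n=n,
        theta_mean=(k + 1.0) / (n + 2.0),
        hdi_95=_beta_hdi(a, b),
        bf10=bf10,
        evidence=classify_bf(bf10),
        posterior=post,
    )


def discrimination_bf10_bruteforce(k: int, n: int) -> float:
    """Independent oracle: BF10 by numerical marginal-likelihood integration.

    p(K|H1) = integral of Binomial(K; N, theta) over the uniform prior,
    p(K|H0) = Binomial(K; N, 1/2); the binomial coefficient cancels, so
    BF10 = int theta^K (1-theta)^(N-K) dtheta / 0.5^N.  The integrand is
    scaled by its mode and integrated adaptively; everything is assembled in
    log space so extreme K stay finite.
    """
    from scipy import integrate

    if n == 0:
        return 1.0
    th_hat = k / n
    ll_max = (k * math.log(th_hat) if k > 0 else 0.0) + (
        (n - k) * math.log1p(-th_hat) if k < n else 0.0
    )

    def scaled(th: float) -> float:
        if th <= 0.0:
            return 0.0 if k > 0 else math.exp(-ll_max)
        if th >= 1.0:
            return 0.0 if k < n else math.exp(-ll_max)
        return math.exp(k * math.log(th) + (n - k) * math.log1p(-th) - ll_max)

    val, _ = integrate.quad(scaled, 0.0, 1.0, points=[th_hat], limit=200,
                            epsabs=0.0, epsrel=1e-12)
    return float(math.exp(ll_max + math.log(val) + n * math.log(2.0)))


def fit_discrimination_mcmc(
    k: int,
    n: int,
    n_chains: int = 3,
    n_samples: int = 10000,
    n_burn: int = 5000,
    seed: int = 0,
) -> Posterior:
    """Random-walk Metropolis sampler for theta (cross-check of conjugacy)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= K <= N")

    def loglik(th: float) -> float:
        if th <= 0.0 or th >= 1.0:
            return 0.0 if (k == 0 or k == n) and (th in (0.0, 1.0)) else -np.inf
        return k * math.log(th) + (n - k) * math.log1p(-th)

    chains = np.empty((n_chains, n_samples - n_burn))
    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(n_chains)):
        rng = np.random.default_rng(ss)
        th = rng.uniform()
        ll = loglik(th)
        step, acc = 0.2, 0
        for it in range(n_samples):
            prop = th + step * rng.standard_normal()
            prop = abs(prop)
            prop = 2.0 - prop if prop > 1.0 else prop  # reflect into [0, 1]
            llp = loglik(prop)
            if math.log(rng.uniform()) < llp - ll:
                th, ll = prop, llp
                acc += 1
            if it < n_burn and (it + 1) % _ADAPT_EVERY == 0:
                rate = acc / _ADAPT_EVERY
                step = min(0.5, step * math.exp(rate - _TARGET_ACCEPT))
                acc = 0
            if it >= n_burn:
                chains[c, it - n_burn] = th
    return Posterior({"theta": chains}, seed=seed, n_burn=n_burn)


# ---------------------------------------------------------------------------
# localization model
# ---------------------------------------------------------------------------


def join_responses(
    trials: TrialTable, responses: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join a response set to its trial table and split singles/doubles."""
    df = trials.trials.merge(responses, on="trial", how="inner")
    singles = df[df.trial_type == "single"]
    doubles = df[df.trial_type == "double"]
    return singles, doubles


def _condition_labels(conditions: list[tuple[float, float]]) -> list[str]:
    return [f"{dl:g},{fm:g}" for dl, fm in conditions]


def _run_localization_chain(
    Ts, Rs, Td, Dd, Rd, cidx, n_cond_counts, spec, n_samples, n_burn, rng
):
    """One adaptive Metropolis-within-Gibbs chain; returns the kept draws."""
    n_s = Ts.size
    K = n_cond_counts.size
    adapting_limit = n_burn

    # initial state from prior draws (SDs clipped away from zero)
    g = rng.normal(spec.prior_g_mean, spec.prior_g_sd)
    b = rng.normal(spec.prior_b_mean, spec.prior_b_sd)
    sig_s = max(0.5, rng.gamma(spec.prior_sigma_shape, 1.0 / spec.prior_sigma_rate))
    sig_d = np.maximum(
        0.5, rng.gamma(spec.prior_sigma_shape, 1.0 / spec.prior_sigma_rate, size=K)
    )
    w = rng.uniform(0.0, 1.0, size=K)

    # cached sufficient statistics of the current state
    P = w[cidx] * Td + (1.0 - w[cidx]) * Dd          # WA predictor per double
    r_d = Rd - g * P - b
    sse_c = np.bincount(cidx, weights=r_d * r_d, minlength=K)
    r_s = Rs - g * Ts - b
    sse_s = float(r_s @ r_s)

    def logprior_g(x):
        return -0.5 * ((x - spec.prior_g_mean) / spec.prior_g_sd) ** 2

    def logprior_b(x):
        return -0.5 * ((x - spec.prior_b_mean) / spec.prior_b_sd) ** 2

    steps = {"g": 0.05, "b": 1.0, "ls": 0.1}
    step_w = np.full(K, 0.1)
    step_lsd = np.full(K, 0.1)
    acc = {"g": 0, "b": 0, "ls": 0}
    acc_w = np.zeros(K)
    acc_lsd = np.zeros(K)

    n_kept = n_samples - n_burn
    out = np.empty((n_kept, 3 + 2 * K))

    inv2_sd = 1.0 / (2.0 * sig_d**2)
    for it in range(n_samples):
        # ---- gain g (touches every trial)
        gp = g + steps["g"] * rng.standard_normal()
        r_dp = Rd - gp * P - b
        sse_cp = np.bincount(cidx, weights=r_dp * r_dp, minlength=K)
        r_sp = Rs - gp * Ts - b
        sse_sp = float(r_sp @ r_sp)
        delta = (
            logprior_g(gp) - logprior_g(g)
            - (sse_sp - sse_s) / (2.0 * sig_s**2)
            - float((sse_cp - sse_c) @ inv2_sd)
        )
        if math.log(rng.uniform()) < delta:
            g, sse_s, sse_c = gp, sse_sp, sse_cp
            acc["g"] += 1

        # ---- bias b (touches every trial)
        bp = b + steps["b"] * rng.standard_normal()
        r_dp = Rd - g * P - bp
        sse_cp = np.bincount(cidx, weights=r_dp * r_dp, minlength=K)
        r_sp = Rs - g * Ts - bp
        sse_sp = float(r_sp @ r_sp)
        delta = (
            logprior_b(bp) - logprior_b(b)
            - (sse_sp - sse_s) / (2.0 * sig_s**2)
            - float((sse_cp - sse_c) @ inv2_sd)
        )
        if math.log(rng.uniform()) < delta:
            b, sse_s, sse_c = bp, sse_sp, sse_cp
            acc["b"] += 1

        # ---- sigma_s (log-scale walk with Jacobian)
        ls = math.log(sig_s)
        lsp = ls + steps["ls"] * rng.standard_normal()
        sp = math.exp(lsp)
        delta = (
            -n_s * (lsp - ls)
            - sse_s / 2.0 * (1.0 / sp**2 - 1.0 / sig_s**2)
            + float(spec.logp_sigma(sp) - spec.logp_sigma(sig_s))
            + (lsp - ls)
        )
        if math.log(rng.uniform()) < delta:
            sig_s = sp
            acc["ls"] += 1

        # ---- weights, blocked across conditions (independent given g, b)
        wp = w + step_w * rng.standard_normal(K)
        wp = np.abs(wp)
        wp = np.where(wp > 1.0, 2.0 - wp, wp)  # reflect into [0, 1]
        Pp = wp[cidx] * Td + (1.0 - wp[cidx]) * Dd
        r_dp = Rd - g * Pp - b
        sse_cp = np.bincount(cidx, weights=r_dp * r_dp, minlength=K)
        delta_c = -(sse_cp - sse_c) * inv2_sd
        accept = np.log(rng.uniform(size=K)) < delta_c
        if np.any(accept):
            w = np.where(accept, wp, w)
            mask = accept[cidx]
            P[mask] = Pp[mask]
            sse_c = np.where(accept, sse_cp, sse_c)
            acc_w += accept

        # ---- sigma_d, blocked across conditions
        lsd = np.log(sig_d)
        lsdp = lsd + step_lsd * rng.standard_normal(K)
        sdp = np.exp(lsdp)
        delta_c = (
            -n_cond_counts * (lsdp - lsd)
            - sse_c / 2.0 * (1.0 / sdp**2 - 1.0 / sig_d**2)
            + spec.logp_sigma(sdp) - spec.logp_sigma(sig_d)
            + (lsdp - lsd)
        )
        accept = np.log(rng.uniform(size=K)) < delta_c
        if np.any(accept):
            sig_d = np.where(accept, sdp, sig_d)
            inv2_sd = 1.0 / (2.0 * sig_d**2)
            acc_lsd += accept

        # ---- step-size adaptation (burn-in only)
        if it < adapting_limit and (it + 1) % _ADAPT_EVERY == 0:
            for key in steps:
                rate = acc[key] / _ADAPT_EVERY
                steps[key] *= math.exp(rate - _TARGET_ACCEPT)
                acc[key] = 0
            step_w = np.minimum(0.5, step_w * np.exp(acc_w / _ADAPT_EVERY - _TARGET_ACCEPT))
            step_lsd = np.minimum(2.0, step_lsd * np.exp(acc_lsd / _ADAPT_EVERY - _TARGET_ACCEPT))
            acc_w[:] = 0.0
            acc_lsd[:] = 0.0

        if it >= n_burn:
            j = it - n_burn
            out[j, 0] = g
            out[j, 1] = b
            out[j, 2] = sig_s
            out[j, 3 : 3 + K] = w
            out[j, 3 + K :] = sig_d
    return out


def fit_localization(
    single_responses: pd.DataFrame,
    double_responses: pd.DataFrame,
    spec: LocalizationModelSpec | None = None,
    n_chains: int = 3,
    n_samples: int = 10000,
    n_burn: int = 5000,
    seed: int = 0,
) -> Posterior:
    """Fit the joint weighted-average localization model by MCMC.

    Parameters
    ----------
    single_responses : DataFrame
        Columns ``target_el`` and ``response_el`` (one listener's singles).
    double_responses : DataFrame
        Columns ``target_el``, ``distractor_el``, ``delta_l_db``, ``fm_hz``
        and ``response_el``; each (delta_l_db, fm_hz) pair becomes a
        condition with its own weight and SD.
    n_chains, n_samples, n_burn
        Defaults follow the analysis protocol: 3 chains of 10000 samples,
        first 5000 discarded as burn-in.

    Returns a :class:`Posterior` over ``g``, ``b``, ``sigma_s`` and, per
    condition c, ``w[c]`` and ``sigma_d[c]``.
    """
    spec = spec or LocalizationModelSpec()
    if len(single_responses) == 0 or len(double_responses) == 0:
        raise ValueError("need both single- and double-sound responses")
    if n_burn >= n_samples:
        raise ValueError("n_burn must be smaller than n_samples")
    Ts = single_responses.target_el.to_numpy(float)
    Rs = single_responses.response_el.to_numpy(float)
    Td = double_responses.target_el.to_numpy(float)
    Dd = double_responses.distractor_el.to_numpy(float)
    Rd = double_responses.response_el.to_numpy(float)
    for arr, name in ((Ts, "single target"), (Rs, "single response"),
                      (Td, "double target"), (Dd, "double distractor"),
                      (Rd, "double response")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name} column")

    cond_df = double_responses[["delta_l_db", "fm_hz"]].astype(float)
    conditions = sorted(set(map(tuple, cond_df.to_numpy())))
    cond_index = {c: i for i, c in enumerate(conditions)}
    cidx = np.array([cond_index[tuple(r)] for r in cond_df.to_numpy()])
    counts = np.bincount(cidx, minlength=len(conditions)).astype(float)
    if np.any(counts == 0):
        empty = [conditions[i] for i in np.where(counts == 0)[0]]
        raise ValueError(f"empty condition cells: {empty}")

    K = len(conditions)
    kept = n_samples - n_burn
    draws = np.empty((n_chains, kept, 3 + 2 * K))
    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(n_chains)):
        rng = np.random.default_rng(ss)
        draws[c] = _run_localization_chain(
            Ts, Rs, Td, Dd, Rd, cidx, counts, spec, n_samples, n_burn, rng
        )

    labels = _condition_labels(conditions)
    samples = {"g": draws[:, :, 0], "b": draws[:, :, 1], "sigma_s": draws[:, :, 2]}
    for i, lab in enumerate(labels):
        samples[f"w[{lab}]"] = draws[:, :, 3 + i]
    for i, lab in enumerate(labels):
        samples[f"sigma_d[{lab}]"] = draws[:, :, 3 + K + i]
    return Posterior(samples, seed=seed, n_burn=n_burn, conditions=conditions)


def fit_single_predictor(
    predictor_el: np.ndarray,
    responses: np.ndarray,
    spec: LocalizationModelSpec | None = None,
    n_chains: int = 3,
    n_samples: int = 6000,
    n_burn: int = 3000,
    seed: int = 0,
) -> Posterior:
    """Bayesian simple linear regression R ~ Normal(g*x + b, sigma).

    Used for single-predictor rows of stimulus-response analyses: target vs
    response, distractor vs response, or the weighted-average prediction vs
    response (with the WA values passed as the predictor).
    """
    spec = spec or LocalizationModelSpec()
    x = np.asarray(predictor_el, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("predictor and response lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    n = x.size

    kept = n_samples - n_burn
    chains = np.empty((n_chains, kept, 3))
    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(n_chains)):
        rng = np.random.default_rng(ss)
        g = rng.normal(spec.prior_g_mean, spec.prior_g_sd)
        b = rng.normal(spec.prior_b_mean, spec.prior_b_sd)
        sig = max(0.5, rng.gamma(spec.prior_sigma_shape, 1.0 / spec.prior_sigma_rate))
        r = y - g * x - b
        sse = float(r @ r)
        steps = {"g": 0.05, "b": 1.0, "ls": 0.2}
        acc = {"g": 0, "b": 0, "ls": 0}
        for it in range(n_samples):
            gp = g + steps["g"] * rng.standard_normal()
            rp = y - gp * x - b
            ssep = float(rp @ rp)
            delta = (
                -0.5 * ((gp - spec.prior_g_mean) ** 2 - (g - spec.prior_g_mean) ** 2)
                / spec.prior_g_sd**2
                - (ssep - sse) / (2.0 * sig**2)
            )
            if math.log(rng.uniform()) < delta:
                g, sse = gp, ssep
                acc["g"] += 1
            bp = b + steps["b"] * rng.standard_normal()
            rp = y - g * x - bp
            ssep = float(rp @ rp)
            delta = (
                -0.5 * ((bp - spec.prior_b_mean) ** 2 - (b - spec.prior_b_mean) ** 2)
                / spec.prior_b_sd**2
                - (ssep - sse) / (2.0 * sig**2)
            )
            if math.log(rng.uniform()) < delta:
                b, sse = bp, ssep
                acc["b"] += 1
            ls = math.log(sig)
            lsp = ls + steps["ls"] * rng.standard_normal()
            sp = math.exp(lsp)
            delta = (
                -n * (lsp - ls)
                - sse / 2.0 * (1.0 / sp**2 - 1.0 / sig**2)
                + float(spec.logp_sigma(sp) - spec.logp_sigma(sig))
                + (lsp - ls)
            )
            if math.log(rng.uniform()) < delta:
                sig = sp
                acc["ls"] += 1
            if it < n_burn and (it + 1) % _ADAPT_EVERY == 0:
                for key in steps:
                    steps[key] *= math.exp(acc[key] / _ADAPT_EVERY - _TARGET_ACCEPT)
                    acc[key] = 0
            if it >= n_burn:
                chains[c, it - n_burn] = (g, b, sig)
    return Posterior(
        {"g": chains[:, :, 0], "b": chains[:, :, 1], "sigma": chains[:, :, 2]},
        seed=seed,
        n_burn=n_burn,
    )
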