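"""Random-effects meta-analysis of city-specific pollution effects.

Normal-normal hierarchy: observed estimates are normal around latent
city effects, which are normal around a pooled mean with heterogeneity
tau. A Gibbs sampler (conjugate for the latent effects and the pooled
mean, adaptive Metropolis on log tau) yields joint posterior draws; a
posterior-predictive draw supplies the effect for municipalities without
their own estimate. Effects are stored as log relative risk per 1 ug/m^3.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._mcmc import split_rhat

__all__ = [
    "CityEffectEstimate",
    "MetaPriors",
    "MetaConfig",
    "MetaDraws",
    "fit_meta",
    "fixed_effect_posterior",
    "predictive_effect",
    "assign_effects",
    "percent_per_10ug",
    "beta_from_percent_per_10ug",
]


@dataclasses.dataclass
class CityEffectEstimate:
    city_id: str
    estimate: float  # log RR per 1 ug/m^3, lag 0-1
    standard_error: float

    def __post_init__(self) -> None:
        if self.standard_error <= 0:
            raise ValueError("standard_error must be positive")


@dataclasses.dataclass
class MetaPriors:
    mu_mean: float = 0.0
    mu_sd: float = 1.0
    tau_scale: float = 0.01  # half-normal scale; 0 collapses to fixed-effect


@dataclasses.dataclass
class MetaConfig:
    seed: int
    n_chains: int = 2
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1


@dataclasses.dataclass
class MetaDraws:
    mu: np.ndarray
    tau: np.ndarray
    theta: np.ndarray  # (n_draws, n_cities)
    city_ids: list[str]
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return len(self.mu)


def fixed_effect_posterior(
    estimates: list[CityEffectEstimate], priors: MetaPriors | None = None
) -> tuple[float, float]:
    """Exact posterior (mean, variance) of the common effect when tau = 0.

    With a flat prior this is the precision-weighted mean with variance
    1 / sum(1 / se^2).
    """
    priors = priors or MetaPriors()
    est = np.array([e.estimate for e in estimates])
    se = np.array([e.standard_error for e in estimates])
    prec = float(np.sum(1.0 / se**2)) + 1.0 / priors.mu_sd**2
    mean = (float(np.sum(est / se**2)) + priors.mu_mean / priors.mu_sd**2) / prec
    return mean, 1.0 / prec


def fit_meta(
    estimates: list[CityEffectEstimate],
    priors: MetaPriors | None = None,
    config: MetaConfig | None = None,
) -> MetaDraws:
    """Gibbs sampling of (mu, tau, theta_1..theta_K)."""
    priors = priors or MetaPriors()
    if config is None:
        raise ValueError("config with a seed is required")
    k = len(estimates)
    if k < 2:
        raise ValueError("need at least 2 cities to identify heterogeneity")
    est = np.array([e.estimate for e in estimates])
    se2 = np.array([e.standard_error for e in estimates]) ** 2
    city_ids = [e.city_id for e in estimates]

    if priors.tau_scale == 0.0:
        # degenerate fixed-effect model: exact conjugate sampling
        mean, var = fixed_effect_posterior(estimates, priors)
        rng = np.random.default_rng(config.seed)
        n_total = config.n_chains * config.n_samples
        mu = rng.normal(mean, math.sqrt(var), n_total)
        theta = np.tile(mu[:, None], (1, k))
        return MetaDraws(
            mu=mu,
            tau=np.zeros(n_total),
            theta=theta,
            city_ids=city_ids,
            diagnostics={"rhat_mu": 1.0, "rhat_tau": 1.0},
        )

    ss = np.random.SeedSequence(config.seed)
    mu_chains, tau_chains, theta_chains = [], [], []
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        mu = float(np.mean(est))
        log_tau = math.log(max(float(np.std(est)), priors.tau_scale / 10))
        theta = est.copy()
        step = 0.5
        keep_mu, keep_tau, keep_theta = [], [], []
        n_iter = config.n_warmup + config.n_samples * config.thin
        for it in range(n_iter):
            tau2 = math.exp(2 * log_tau)
            # theta_k | rest: conjugate normal
            prec = 1.0 / se2 + 1.0 / tau2
            mean = (est / se2 + mu / tau2) / prec
            theta = mean + rng.standard_normal(k) / np.sqrt(prec)
            # mu | rest: conjugate normal
            prec_mu = k / tau2 + 1.0 / priors.mu_sd**2
            mean_mu = (theta.sum() / tau2 + priors.mu_mean / priors.mu_sd**2) / prec_mu
            mu = mean_mu + rng.standard_normal() / math.sqrt(prec_mu)
            # log tau: adaptive random walk
            def lp(lt: float) -> float:
                t2 = math.exp(2 * lt)
                ll = -0.5 * k * math.log(t2) - float(((theta - mu) ** 2).sum()) / (2 * t2)
                # half-normal on tau plus the log-Jacobian of tau -> log tau
                return ll - math.exp(2 * lt) / (2 * priors.tau_scale**2) + lt

            prop = log_tau + step * rng.standard_normal()
            acc = math.log(rng.uniform()) < lp(prop) - lp(log_tau)
            if acc:
                log_tau = prop
            if it < config.n_warmup:
                step *= math.exp((float(acc) - 0.44) * min(0.25, 5.0 / math.sqrt(it + 1)))
            elif (it - config.n_warmup) % config.thin == 0:
                keep_mu.append(mu)
                keep_tau.append(math.exp(log_tau))
                keep_theta.append(theta.copy())
        mu_chains.append(np.array(keep_mu))
        tau_chains.append(np.array(keep_tau))
        theta_chains.append(np.array(keep_theta))

    diagnostics = {
        "rhat_mu": split_rhat(np.stack(mu_chains)),
        "rhat_tau": split_rhat(np.stack(tau_chains)),
    }
    return MetaDraws(
        mu=np.concatenate(mu_chains),
        tau=np.concatenate(tau_chains),
        theta=np.concatenate(theta_chains),
        city_ids=city_ids,
        diagnostics=diagnostics,
    )


def predictive_effect(
    draws: MetaDraws, n_new: int, seed: int, shared: bool = True
) -> np.ndarray:
    """Posterior-predictive effect draws for cities without an estimate.

    Per MC iteration a new effect is drawn from N(mu, tau^2). With
    ``shared=True`` (default) one draw per iteration is broadcast to all
    ``n_new`` municipalities, preserving between-municipality correlation;
    otherwise each municipality gets an independent draw.
    """
    rng = np.random.default_rng(seed)
    if shared:
        new = rng.normal(draws.mu, draws.tau)
        return np.tile(new[:, None], (1, n_new))
    return rng.normal(draws.mu[:, None], draws.tau[:, None], (draws.n_draws, n_new))


def assign_effects(
    n_munis: int,
    known_city_map: dict[int, str],
    meta_draws: MetaDraws,
    generic_draws: np.ndarray,
) -> np.ndarray:
    """Draw-aligned (n_draws, n_munis) effect matrix.

    Municipalities in ``known_city_map`` receive their city's posterior
    draws; all others receive posterior-predictive generic draws.
    """
    if generic_draws.shape != (meta_draws.n_draws, n_munis):
        raise ValueError("generic_draws must be (n_draws, n_munis)")
    out = generic_draws.copy()
    index = {cid: j for j, cid in enumerate(meta_draws.city_ids)}
    for muni, cid in known_city_map.items():
        if cid not in index:
            raise KeyError(f"unknown city id {cid!r}")
        out[:, muni] = meta_draws.theta[:, index[cid]]
    return out


def percent_per_10ug(beta) -> np.ndarray:
    """Convert log RR per 1 ug/m^3 to percent mortality variation per 10 ug/m^3."""
    return 100.0 * np.expm1(10.0 * np.asarray(beta, dtype=float))


def beta_from_percent_per_10ug(percent) -> np.ndarray:
    return np.log1p(np.asarray(percent, dtype=float) / 100.0) / 10.0
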