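"""Disease-mapping smoother for municipality mortality rates.

Poisson counts with a log-linear rate decomposed into an intercept, an
exchangeable (unstructured) normal effect and an intrinsic CAR (spatially
structured) effect constrained to sum to zero; inverse-gamma priors on both
variance components. Sampling is Metropolis-within-Gibbs: elementwise
adaptive random-walk updates for the random effects (the CAR field is
updated in conflict-free color blocks so each block update is exact),
conjugate inverse-gamma updates for the variances.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from ._mcmc import greedy_coloring, split_rhat

__all__ = [
    "BymConfig",
    "RateSamples",
    "icar_conditional",
    "fit_bym",
    "smoothed_vs_crude_report",
]


@dataclasses.dataclass
class BymConfig:
    seed: int
    tau_shape: float = 0.5
    tau_rate: float = 0.0005
    intercept_sd: float = 10.0
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1

    def validate(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples, self.thin) < 1:
            raise ValueError("chain counts must be positive")
        if self.tau_shape <= 0 or self.tau_rate <= 0 or self.intercept_sd <= 0:
            raise ValueError("prior parameters must be positive")


@dataclasses.dataclass
class RateSamples:
    draws: np.ndarray  # (n_draws, n_munis) rates, deaths per person-year
    tau_u2: np.ndarray
    tau_v2: np.ndarray
    intercept: np.ndarray
    v_draws: np.ndarray
    diagnostics: dict
    n_chains: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def icar_conditional(
    v: np.ndarray, i: int, adjacency: list[np.ndarray], tau_v2: float
) -> tuple[float, float]:
    """Full conditional (mean, variance) of the CAR effect at node ``i``.

    Isolated nodes have no conditional information: by contract the sampler
    fixes their effect at zero, signalled here by (0.0, inf).
    """
    nbrs = adjacency[i]
    if len(nbrs) == 0:
        return 0.0, math.inf
    return float(np.mean(np.asarray(v)[nbrs])), tau_v2 / len(nbrs)


def _edge_sse(v: np.ndarray, adjacency: list[np.ndarray]) -> float:
    sse = 0.0
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            if j > i:
                sse += (v[i] - v[j]) ** 2
    return sse


def _n_components(adjacency: list[np.ndarray], nodes: np.ndarray) -> int:
    todo = set(int(i) for i in nodes)
    comps = 0
    while todo:
        comps += 1
        stack = [todo.pop()]
        while stack:
            i = stack.pop()
            for j in adjacency[i]:
                if j in todo:
                    todo.remove(int(j))
                    stack.append(int(j))
    return comps


def fit_bym(
    deaths: np.ndarray,
    person_years: np.ndarray,
    adjacency: list[np.ndarray],
    config: BymConfig,
) -> RateSamples:
    """Posterior sampling of smoothed mortality rates."""
    config.validate()
    deaths = np.asarray(deaths, dtype=float)
    py = np.asarray(person_years, dtype=float)
    n = len(deaths)
    if np.any(deaths < 0):
        raise ValueError("deaths must be nonnegative")
    if np.any(py <= 0):
        raise ValueError("person_years must be positive")
    adjacency = [np.asarray(a, dtype=np.int64) for a in adjacency]

    noniso = np.array([len(a) > 0 for a in adjacency])
    noniso_idx = np.flatnonzero(noniso)
    colors = [c[noniso[c]] for c in greedy_coloring(adjacency)]
    colors = [c for c in colors if len(c)]
    rank = int(noniso.sum()) - (_n_components(adjacency, noniso_idx) if noniso.any() else 0)
    n_i = np.array([len(a) for a in adjacency], dtype=float)

    a0_init = math.log((deaths.sum() + 0.5) / py.sum())
    ss = np.random.SeedSequence(config.seed)
    rate_chains, tu_chains, tv_chains, a0_chains, v_chains = [], [], [], [], []

    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        a0 = a0_init + rng.normal(0, 0.1)
        u = np.zeros(n)
        v = np.zeros(n)
        tu2, tv2 = 0.1, 0.1
        s_u = np.full(n, 0.3)
        s_v = np.full(n, 0.3)
        s_a = 0.1

        keep_r, keep_tu, keep_tv, keep_a0, keep_v = [], [], [], [], []
        n_iter = config.n_warmup + config.n_samples * config.thin
        for it in range(n_iter):
            adapt = min(0.25, 5.0 / math.sqrt(it + 1)) if it < config.n_warmup else 0.0

            # exchangeable effects: conditionally independent, update jointly
            eta = a0 + u + v
            prop = u + s_u * rng.standard_normal(n)
            eta_p = a0 + prop + v
            dlog = (
                deaths * (eta_p - eta)
                - py * (np.exp(eta_p) - np.exp(eta))
                - (prop**2 - u**2) / (2 * tu2)
            )
            acc = np.log(rng.uniform(size=n)) < dlog
            u = np.where(acc, prop, u)
            if adapt:
                s_u *= np.exp((acc - 0.44) * adapt)

            # CAR effects: update one color class at a time (no shared edges)
            for cls in colors:
                nb_mean = np.array([v[adjacency[i]].mean() for i in cls])
                eta_c = a0 + u[cls] + v[cls]
                prop = v[cls] + s_v[cls] * rng.standard_normal(len(cls))
                eta_p = a0 + u[cls] + prop
                dlog = (
                    deaths[cls] * (eta_p - eta_c)
                    - py[cls] * (np.exp(eta_p) - np.exp(eta_c))
                    - n_i[cls] * ((prop - nb_mean) ** 2 - (v[cls] - nb_mean) ** 2) / (2 * tv2)
                )
                acc = np.log(rng.uniform(size=len(cls))) < dlog
                v[cls] = np.where(acc, prop, v[cls])
                if adapt:
                    s_v[cls] *= np.exp((acc - 0.44) * adapt)

            # sweep the CAR level into the intercept (sum-to-zero constraint)
            if len(noniso_idx):
                shift = v[noniso_idx].mean()
                v[noniso_idx] -= shift
                a0 += shift

            # intercept
            prop = a0 + s_a * rng.standard_normal()
            eta = a0 + u + v
            eta_p = prop + u + v
            dlog = float(
                np.sum(deaths * (eta_p - eta) - py * (np.exp(eta_p) - np.exp(eta)))
            ) - (prop**2 - a0**2) / (2 * config.intercept_sd**2)
            acc_a = math.log(rng.uniform()) < dlog
            if acc_a:
                a0 = prop
            if adapt:
                s_a *= math.exp((float(acc_a) - 0.44) * adapt)

            # conjugate inverse-gamma updates
            tu2 = (config.tau_rate + 0.5 * float(u @ u)) / rng.gamma(
                config.tau_shape + 0.5 * n
            )
            sse = _edge_sse(v, adjacency)
            tv2 = (config.tau_rate + 0.5 * sse) / rng.gamma(config.tau_shape + 0.5 * rank) \
                if rank > 0 else config.tau_rate / rng.gamma(config.tau_shape)

            if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
                keep_r.append(np.exp(a0 + u + v))
                keep_tu.append(tu2)
                keep_tv.append(tv2)
                keep_a0.append(a0)
                keep_v.append(v.copy())

        rate_chains.append(np.array(keep_r))
        tu_chains.append(np.array(keep_tu))
        tv_chains.append(np.array(keep_tv))
        a0_chains.append(np.array(keep_a0))
        v_chains.append(np.array(keep_v))

    rates = np.concatenate(rate_chains)
    diagnostics = {
        "rhat_rates": np.array(
            [split_rhat(np.stack([c[:, i] for c in rate_chains])) for i in range(n)]
        ),
        "rhat_tau_u2": split_rhat(np.stack(tu_chains)),
        "rhat_tau_v2": split_rhat(np.stack(tv_chains)),
        "rhat_intercept": split_rhat(np.stack(a0_chains)),
    }
    bad = np.flatnonzero(diagnostics["rhat_rates"] > 1.05)
    if len(bad):
        warnings.warn(f"possible non-convergence for rate indices {bad.tolist()}")
    return RateSamples(
        draws=rates,
        tau_u2=np.concatenate(tu_chains),
        tau_v2=np.concatenate(tv_chains),
        intercept=np.concatenate(a0_chains),
        v_draws=np.concatenate(v_chains),
        diagnostics=diagnostics,
        n_chains=config.n_chains,
    )


def smoothed_vs_crude_report(
    samples: RateSamples, deaths: np.ndarray, person_years: np.ndarray
) -> pd.DataFrame:
    """Per-municipality comparison of crude and smoothed rates."""
    deaths = np.asarray(deaths, dtype=float)
    py = np.asarray(person_years, dtype=float)
    crude = deaths / py
    pooled = deaths.sum() / py.sum()
    post_mean = samples.draws.mean(axis=0)
    post_median = np.percentile(samples.draws, 50, axis=0)
    lo, hi = np.percentile(samples.draws, [10, 90], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(
            crude != pooled, (post_mean - pooled) / (crude - pooled), np.nan
        )
    return pd.DataFrame(
        {
            "municipality_id": np.arange(len(deaths)),
            "crude_rate": crude,
            "posterior_mean": post_mean,
            "posterior_median": post_median,
            "cri_10": lo,
            "cri_90": hi,
            "shrinkage_factor": shrink,
        }
    )
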