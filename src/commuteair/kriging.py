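"""Bayesian universal kriging of annual PM10.

Calibrates sparse monitor observations (on the log scale) against
deterministic-model grid predictions with a Gaussian-process residual whose
correlation is exp(-phi * d^kappa), then draws from the joint posterior
predictive at every grid cell and aggregates to municipalities.

The sampler alternates a conjugate GLS update for the regression
coefficients with an adaptive random-walk Metropolis step on
(log sigma^2, kappa, t), where t in [0, 1] indexes the conditional-uniform
prior interval for phi given kappa.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from ._mcmc import split_rhat

__all__ = [
    "KrigingPriors",
    "KrigingConfig",
    "KrigingDraws",
    "correlation",
    "phi_bounds",
    "fit_kriging",
    "predict_cells",
    "aggregate_to_municipality",
    "municipality_weights",
    "fractional_bias",
    "loocv",
    "simulate_log_field",
]


def correlation(d, phi: float, kappa: float):
    """Spatial correlation exp(-phi * d^kappa) for distances ``d`` in km."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if not 0 < kappa <= 2:
        raise ValueError("kappa must be in (0, 2]")
    return np.exp(-phi * d**kappa)


def kappa_min(d_min: float = 3.0, d_max: float = 250.0) -> float:
    """Smallest smoothness exponent compatible with the correlation anchors.

    Correlation >= 0.95 at ``d_min`` and <= 0.05 at ``d_max`` is only
    achievable for kappa above log(log 0.05 / log 0.95) / log(d_max/d_min);
    flatter exponents cannot decay enough between the two anchor distances.
    """
    return float(np.log(np.log(0.05) / np.log(0.95)) / np.log(d_max / d_min))


def phi_bounds(kappa: float, d_min: float = 3.0, d_max: float = 250.0) -> tuple[float, float]:
    """Support of the conditional-uniform prior on phi given kappa.

    Constrains the correlation to be at least 0.95 at ``d_min`` and at most
    0.05 at ``d_max``.
    """
    lo = -np.log(0.05) / d_max**kappa
    hi = -np.log(0.95) / d_min**kappa
    if lo >= hi:
        raise ValueError("empty phi prior support; kappa below kappa_min(d_min, d_max)")
    return lo, hi


@dataclasses.dataclass
class KrigingPriors:
    alpha_mean: float = 0.0
    alpha_sd: float = 100.0
    beta_mean: float = 0.0
    beta_sd: float = 100.0
    sigma_scale: float = 1.0  # half-normal scale on sigma (log concentration)
    d_min: float = 3.0
    d_max: float = 250.0
    nugget: float = 1e-4  # variance on the log scale, numerical stabiliser


@dataclasses.dataclass
class KrigingConfig:
    seed: int
    n_chains: int = 2
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1


@dataclasses.dataclass
class KrigingDraws:
    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    phi: np.ndarray
    kappa: np.ndarray
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return len(self.alpha)


def _mvn_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    c, low = cho_factor(cov, lower=True)
    half = solve_triangular(c, resid, lower=True)
    return -0.5 * float(half @ half) - float(np.log(np.diag(c)).sum())


def fit_kriging(
    monitor_logs: np.ndarray,
    z_s: np.ndarray,
    distances: np.ndarray,
    priors: KrigingPriors | None = None,
    config: KrigingConfig | None = None,
) -> KrigingDraws:
    """MCMC over (alpha, beta, sigma2, phi, kappa) given monitor log values."""
    priors = priors or KrigingPriors()
    if config is None:
        raise ValueError("config with a seed is required")
    y = np.asarray(monitor_logs, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    distances = np.asarray(distances, dtype=float)
    m = len(y)
    if m < 3:
        raise ValueError("need at least 3 monitors")
    if distances.shape != (m, m) or np.any(np.abs(np.diag(distances)) > 0):
        raise ValueError("distances must be square with zero diagonal")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    off = distances[~np.eye(m, dtype=bool)]
    if np.any(off == 0):
        warnings.warn("duplicate monitor locations; jittering distances")
        distances = distances + 1e-6 * (1 - np.eye(m))

    X = np.column_stack([np.ones(m), z_s])
    prior_prec = np.diag([priors.alpha_sd**-2, priors.beta_sd**-2])
    prior_mean = np.array([priors.alpha_mean, priors.beta_mean])

    ss = np.random.SeedSequence(config.seed)
    chains = {k: [] for k in ("alpha", "beta", "sigma2", "phi", "kappa")}

    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        # crude least-squares init
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid0 = y - X @ coef
        theta = np.log(max(float(resid0.var()), 1e-6))  # log sigma2
        kap_lo = kappa_min(priors.d_min, priors.d_max)
        kappa = min(max(1.0, kap_lo + 0.3), 2.0)
        t = 0.5
        step = np.array([0.5, 0.3, 0.3])
        coefs = coef.copy()

        def cov_of(theta_, kappa_, t_):
            lo, hi = phi_bounds(kappa_, priors.d_min, priors.d_max)
            phi_ = lo + t_ * (hi - lo)
            cov = np.exp(theta_) * correlation(distances, phi_, kappa_)
            cov[np.diag_indices_from(cov)] += priors.nugget + 1e-12
            return cov, phi_

        def log_post_cov(theta_, kappa_, t_, coefs_):
            cov, _ = cov_of(theta_, kappa_, t_)
            ll = _mvn_loglik(y - X @ coefs_, cov)
            sigma2 = np.exp(theta_)
            # half-normal prior on sigma expressed in theta = log sigma2
            lp = -sigma2 / (2 * priors.sigma_scale**2) + 0.5 * theta_
            return ll + lp

        lp_cur = log_post_cov(theta, kappa, t, coefs)
        keep = {k: [] for k in chains}
        n_iter = config.n_warmup + config.n_samples * config.thin
        acc = 0.0
        for it in range(n_iter):
            # conjugate GLS update of (alpha, beta)
            cov, phi = cov_of(theta, kappa, t)
            c = cho_factor(cov, lower=True)
            XtSi = cho_solve(c, X).T
            prec = XtSi @ X + prior_prec
            mean = np.linalg.solve(prec, XtSi @ y + prior_prec @ prior_mean)
            L = cholesky(np.linalg.inv(prec), lower=True)
            coefs = mean + L @ rng.standard_normal(2)
            lp_cur = log_post_cov(theta, kappa, t, coefs)

            # joint RW-MH on (log sigma2, kappa, t)
            prop = np.array([theta, kappa, t]) + step * rng.standard_normal(3)
            if kap_lo < prop[1] <= 2 and 0 < prop[2] < 1:
                lp_prop = log_post_cov(prop[0], prop[1], prop[2], coefs)
                if np.log(rng.uniform()) < lp_prop - lp_cur:
                    theta, kappa, t = prop
                    lp_cur = lp_prop
                    acc = 1.0
                else:
                    acc = 0.0
            else:
                acc = 0.0
            if it < config.n_warmup:
                step *= np.exp((acc - 0.25) * min(0.1, 3.0 / np.sqrt(it + 1)))
            elif (it - config.n_warmup) % config.thin == 0:
                _, phi = cov_of(theta, kappa, t)
                keep["alpha"].append(coefs[0])
                keep["beta"].append(coefs[1])
                keep["sigma2"].append(np.exp(theta))
                keep["phi"].append(phi)
                keep["kappa"].append(kappa)
        for k in chains:
            chains[k].append(np.array(keep[k]))

    diagnostics = {
        f"rhat_{k}": split_rhat(np.stack(chains[k])) for k in chains
    }
    return KrigingDraws(
        alpha=np.concatenate(chains["alpha"]),
        beta=np.concatenate(chains["beta"]),
        sigma2=np.concatenate(chains["sigma2"]),
        phi=np.concatenate(chains["phi"]),
        kappa=np.concatenate(chains["kappa"]),
        diagnostics=diagnostics,
    )


def predict_cells(
    draws: KrigingDraws,
    z_cells: np.ndarray,
    monitor_logs: np.ndarray,
    z_s: np.ndarray,
    dist_cells_monitors: np.ndarray,
    dist_cells_cells: np.ndarray,
    dist_monitors: np.ndarray,
    priors: KrigingPriors | None = None,
    seed: int = 0,
    n_draws: int | None = None,
) -> np.ndarray:
    """Joint conditional-Gaussian simulation of log PM10 at every cell.

    Returns concentrations (exponentiated), shape (n_draws, n_cells). With a
    zero nugget the predictive at a monitor's own cell collapses to the
    observed value in every draw (exact interpolation).
    """
    priors = priors or KrigingPriors()
    y = np.asarray(monitor_logs, dtype=float)
    z_cells = np.asarray(z_cells, dtype=float)
    rng = np.random.default_rng(seed)
    total = draws.n_draws if n_draws is None else min(n_draws, draws.n_draws)
    n_cells = len(z_cells)
    out = np.empty((total, n_cells))
    jitter = 1e-10
    for d in range(total):
        a, b = draws.alpha[d], draws.beta[d]
        s2, phi, kap = draws.sigma2[d], draws.phi[d], draws.kappa[d]
        cov_mm = s2 * correlation(dist_monitors, phi, kap)
        cov_mm[np.diag_indices_from(cov_mm)] += priors.nugget + jitter
        cov_cm = s2 * correlation(dist_cells_monitors, phi, kap)
        cov_cc = s2 * correlation(dist_cells_cells, phi, kap)
        c = cho_factor(cov_mm, lower=True)
        resid = y - (a + b * z_s)
        mean = a + b * z_cells + cov_cm @ cho_solve(c, resid)
        half = solve_triangular(c[0], cov_cm.T, lower=True)
        cond = cov_cc - half.T @ half
        cond[np.diag_indices_from(cond)] += jitter * max(s2, 1.0)
        L = cholesky(cond, lower=True)
        out[d] = mean + L @ rng.standard_normal(n_cells)
    return np.exp(out)


def municipality_weights(
    cell_muni: np.ndarray, n_munis: int, cell_weights: np.ndarray | None = None
) -> np.ndarray:
    """(n_cells, n_munis) column-stochastic aggregation weight matrix."""
    cell_muni = np.asarray(cell_muni)
    w = np.ones(len(cell_muni)) if cell_weights is None else np.asarray(cell_weights, float)
    if np.any(w < 0):
        raise ValueError("cell weights must be nonnegative")
    W = np.zeros((len(cell_muni), n_munis))
    for i in range(n_munis):
        mask = cell_muni == i
        total = w[mask].sum()
        if total <= 0:
            raise ValueError(f"municipality {i} has no grid cells")
        W[mask, i] = w[mask] / total
    return W


def aggregate_to_municipality(cell_draws: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean of cell concentrations per municipality, per draw."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.allclose(weights.sum(axis=0), 1.0):
        raise ValueError("weight columns must sum to 1")
    return np.asarray(cell_draws) @ weights


def fractional_bias(pred: np.ndarray, obs: np.ndarray) -> float:
    """FB in percent: 200 * (mean(pred) - mean(obs)) / (mean(pred) + mean(obs))."""
    mp, mo = float(np.mean(pred)), float(np.mean(obs))
    return 200.0 * (mp - mo) / (mp + mo)


def loocv(
    monitor_logs: np.ndarray,
    z_s: np.ndarray,
    distances: np.ndarray,
    priors: KrigingPriors | None = None,
    config: KrigingConfig | None = None,
    refit: bool = False,
    max_draws: int = 400,
) -> tuple[float, float]:
    """Leave-one-out validation on the log scale: (rmse_log, fb_percent).

    By default reuses the full-data posterior parameter draws and performs
    leave-one-out conditional prediction; ``refit=True`` refits the model
    without each monitor in turn.
    """
    priors = priors or KrigingPriors()
    y = np.asarray(monitor_logs, dtype=float)
    z_s = np.asarray(z_s, dtype=float)
    m = len(y)
    if m < 4:
        raise ValueError("need at least 4 monitors for leave-one-out")
    preds = np.empty(m)
    idx = np.arange(m)
    if refit:
        for i in range(m):
            rest = idx != i
            d = fit_kriging(y[rest], z_s[rest], distances[np.ix_(rest, rest)], priors, config)
            cells = predict_cells(
                d,
                z_s[i : i + 1],
                y[rest],
                z_s[rest],
                distances[i, rest][None, :],
                np.zeros((1, 1)),
                distances[np.ix_(rest, rest)],
                priors,
                seed=config.seed + 1000 + i,
                n_draws=max_draws,
            )
            preds[i] = float(np.log(cells).mean())
        return float(np.sqrt(np.mean((preds - y) ** 2))), fractional_bias(preds, y)

    draws = fit_kriging(y, z_s, distances, priors, config)
    total = min(max_draws, draws.n_draws)
    acc = np.zeros(m)
    for d in range(total):
        a, b = draws.alpha[d], draws.beta[d]
        s2, phi, kap = draws.sigma2[d], draws.phi[d], draws.kappa[d]
        cov = s2 * correlation(distances, phi, kap)
        cov[np.diag_indices_from(cov)] += priors.nugget + 1e-12
        mu = a + b * z_s
        for i in range(m):
            rest = idx != i
            c = cho_factor(cov[np.ix_(rest, rest)], lower=True)
            w = cho_solve(c, y[rest] - mu[rest])
            acc[i] += mu[i] + cov[i, rest] @ w
    preds = acc / total
    return float(np.sqrt(np.mean((preds - y) ** 2))), fractional_bias(preds, y)


def simulate_log_field(
    z: np.ndarray,
    distances: np.ndarray,
    alpha: float,
    beta: float,
    sigma2: float,
    phi: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one log field realization from the kriging generative model."""
    cov = sigma2 * correlation(distances, phi, kappa)
    cov[np.diag_indices_from(cov)] += 1e-10
    mean = alpha + beta * np.asarray(z, dtype=float)
    return rng.multivariate_normal(mean, cov, method="cholesky")
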