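"""Conjugate model for intermunicipality commuting probabilities.

A vague Beta(1, 1) prior on each ordered-pair commuting probability with a
binomial likelihood for the census counts gives the closed-form posterior
Beta(1 + c_ij, 1 + pop_i^2001 - c_ij). Flow draws are beta-binomial: a
probability draw per pair, then a binomial count with the 2007 population
as the number of trials.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "CommutingPosterior",
    "FlowDraws",
    "posterior_from_counts",
    "sample_probabilities",
    "sample_flows",
    "ks_check_beta",
]


@dataclasses.dataclass
class CommutingPosterior:
    a: np.ndarray  # (n, n) beta shape1, diagonal unused
    b: np.ndarray  # (n, n) beta shape2
    pop_2001: np.ndarray

    @property
    def n_munis(self) -> int:
        return len(self.pop_2001)

    def mean(self) -> np.ndarray:
        m = self.a / (self.a + self.b)
        np.fill_diagonal(m, 0.0)
        return m


@dataclasses.dataclass
class FlowDraws:
    draws: np.ndarray  # (n_draws, n, n) int64, zero diagonal
    n_resampled_rows: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def posterior_from_counts(od_counts: np.ndarray, pop_2001: np.ndarray) -> CommutingPosterior:
    """Exact conjugate posterior parameters from census commuting counts."""
    c = np.asarray(od_counts)
    pop = np.asarray(pop_2001)
    n = len(pop)
    if c.shape != (n, n):
        raise ValueError("od_counts must be square, matching pop_2001")
    if np.any(c < 0):
        raise ValueError("od_counts must be nonnegative")
    offdiag = ~np.eye(n, dtype=bool)
    if np.any(c[offdiag] > np.broadcast_to(pop[:, None], (n, n))[offdiag]):
        raise ValueError("od_counts exceed origin population")
    a = 1.0 + c.astype(float)
    b = 1.0 + pop[:, None].astype(float) - c.astype(float)
    return CommutingPosterior(a=a, b=b, pop_2001=pop)


def sample_probabilities(
    posterior: CommutingPosterior, n_draws: int, seed
) -> np.ndarray:
    """Independent Beta draws of p_ij, shape (n_draws, n, n), zero diagonal."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.beta(posterior.a, posterior.b, size=(n_draws, *posterior.a.shape))
    idx = np.arange(posterior.n_munis)
    p[:, idx, idx] = 0.0
    return p


def sample_flows(
    posterior: CommutingPosterior, pop_2007: np.ndarray, n_draws: int, seed
) -> FlowDraws:
    """Beta-binomial flow draws: exit(i, j) ~ Binomial(pop_i^2007, p_ij).

    Rows whose sampled total exits reach the origin population are
    resampled (and counted); at realistic probabilities this never fires.
    """
    pop = np.asarray(pop_2007)
    rng = np.random.default_rng(seed)
    p = sample_probabilities(posterior, n_draws, rng)
    flows = rng.binomial(pop[None, :, None], p)
    idx = np.arange(posterior.n_munis)
    flows[:, idx, idx] = 0
    n_resampled = 0
    bad = np.argwhere(flows.sum(axis=2) >= pop[None, :])
    for d, i in bad:
        n_resampled += 1
        while True:
            pi = rng.beta(posterior.a[i], posterior.b[i])
            pi[i] = 0.0
            row = rng.binomial(pop[i], pi)
            row[i] = 0
            if row.sum() < pop[i]:
                flows[d, i] = row
                break
    return FlowDraws(draws=flows.astype(np.int64), n_resampled_rows=n_resampled)


def ks_check_beta(samples: np.ndarray, a: float, b: float) -> float:
    """Kolmogorov-Smirnov distance to the analytic Beta(a, b) law."""
    samples = np.asarray(samples)
    if samples.size < 100:
        raise ValueError("need at least 100 samples")
    return float(stats.kstest(samples, stats.beta(a, b).cdf).statistic)
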