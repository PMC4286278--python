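"""Shared MCMC utilities: convergence diagnostics and graph coloring."""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "greedy_coloring"]


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_iter). Each chain is split in half,
    then the classic between/within variance ratio is computed. Returns 1.0
    for degenerate (zero-variance) draws.
    """
    chains = np.asarray(chains, dtype=float)
    n_chains, n_iter = chains.shape
    half = n_iter // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def greedy_coloring(adjacency: list[np.ndarray]) -> list[np.ndarray]:
    """Proper vertex coloring; returns index arrays per color class."""
    n = len(adjacency)
    colors = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        used = {colors[j] for j in adjacency[i] if colors[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]
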