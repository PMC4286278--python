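"""Long-format CSV exchange for draw-aligned posterior matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_draw_matrix", "read_draw_matrix", "write_impact_draws", "read_impact_draws"]


def write_draw_matrix(path: str | Path, draws: np.ndarray, value_name: str) -> None:
    """Write (n_draws, n_munis) to CSV columns (draw, municipality_id, value)."""
    draws = np.asarray(draws)
    n_draws, n = draws.shape
    d, m = np.meshgrid(np.arange(n_draws), np.arange(n), indexing="ij")
    pd.DataFrame(
        {"draw": d.ravel(), "municipality_id": m.ravel(), value_name: draws.ravel()}
    ).to_csv(path, index=False)


def read_draw_matrix(path: str | Path, value_name: str) -> np.ndarray:
    df = pd.read_csv(path)
    n_draws = df["draw"].max() + 1
    n = df["municipality_id"].max() + 1
    out = np.full((n_draws, n), np.nan)
    out[df["draw"].to_numpy(), df["municipality_id"].to_numpy()] = df[value_name].to_numpy()
    if np.isnan(out).any():
        raise ValueError(f"missing (draw, municipality) cells in {path}")
    return out


def write_impact_draws(path: str | Path, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
    n_draws, n = a.shape
    d, m = np.meshgrid(np.arange(n_draws), np.arange(n), indexing="ij")
    pd.DataFrame(
        {
            "draw": d.ravel(),
            "municipality_id": m.ravel(),
            "A": a.ravel(),
            "B": b.ravel(),
            "C": c.ravel(),
        }
    ).to_csv(path, index=False)


def read_impact_draws(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    n_draws = df["draw"].max() + 1
    n = df["municipality_id"].max() + 1
    out = []
    for col in ("A", "B", "C"):
        mat = np.full((n_draws, n), np.nan)
        mat[df["draw"].to_numpy(), df["municipality_id"].to_numpy()] = df[col].to_numpy()
        out.append(mat)
    return tuple(out)
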