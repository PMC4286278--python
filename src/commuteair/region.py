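"""Synthetic study regions with known ground truth.

Builds lattice regions of municipalities (each owning a handful of grid
cells), simulates the generative quantities every downstream stage tries to
recover (mortality rates, an annual pollution field, city effects, commuting
probabilities) and produces an observed study (death counts, origin-
destination commuting counts, noisy monitors, deterministic grid
predictions).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .kriging import correlation

__all__ = [
    "RegionGraph",
    "GroundTruth",
    "SyntheticStudy",
    "TruthConfig",
    "make_lattice_region",
    "simulate_truth",
    "observe_study",
    "write_study",
    "read_region",
    "read_od_counts",
    "read_monitors",
    "read_grid",
    "read_city_effects",
]


@dataclasses.dataclass
class RegionGraph:
    """Spatial backbone: municipalities, adjacency, grid cell ownership."""

    populations_2001: np.ndarray
    populations_2007: np.ndarray
    adjacency: list[np.ndarray]
    centroids: np.ndarray
    province_id: np.ndarray
    capital_flag: np.ndarray
    cell_centroids: np.ndarray
    cell_muni: np.ndarray

    @property
    def n_munis(self) -> int:
        return len(self.populations_2001)

    @property
    def n_cells(self) -> int:
        return len(self.cell_muni)

    def validate(self) -> None:
        n = self.n_munis
        if len(self.adjacency) != n:
            raise ValueError("adjacency length mismatch")
        if np.any(self.populations_2001 < 1) or np.any(self.populations_2007 < 1):
            raise ValueError("populations must be >= 1")
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError(f"self-neighbor at {i}")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric adjacency {i}-{j}")
        for p in np.unique(self.province_id):
            members = np.flatnonzero(self.province_id == p)
            if self.capital_flag[members].sum() != 1:
                raise ValueError(f"province {p} must have exactly one capital")


@dataclasses.dataclass
class GroundTruth:
    """Generating values used by recovery tests."""

    true_rates: np.ndarray
    true_field_cells: np.ndarray
    true_field_munis: np.ndarray
    true_effects: np.ndarray
    true_commuting_probs: np.ndarray
    cell_z: np.ndarray
    conc_params: dict


@dataclasses.dataclass
class SyntheticStudy:
    """Observed data emitted for the pipeline, plus the generating truth."""

    region: RegionGraph
    deaths_5yr: np.ndarray
    od_counts: np.ndarray
    monitor_cells: np.ndarray
    monitor_values: np.ndarray
    grid_z: np.ndarray
    city_effect_ids: np.ndarray
    city_effect_estimates: np.ndarray
    city_effect_ses: np.ndarray
    truth: GroundTruth


@dataclasses.dataclass
class TruthConfig:
    """Generative parameters for :func:`simulate_truth`.

    Concentration parameters define the log field as a linear calibration of
    the deterministic grid prediction ``z`` plus a spatially correlated
    Gaussian residual, so the kriging stage is exactly well specified.
    """

    baseline_log_rate: float = math.log(0.01)
    tau_u2: float = 0.01
    tau_v2: float = 0.04
    effect_mean: float = 0.0008
    effect_sd: float = 0.0004
    gravity_decay_km: float = 12.0
    gravity_gamma: float = 0.8
    capital_boost: float = 3.0
    p_max: float = 0.45
    commute_frac_range: tuple[float, float] = (0.20, 0.40)
    capital_commute_frac_range: tuple[float, float] = (0.05, 0.10)
    conc_base: float = 25.0
    conc_amp: float = 15.0
    conc_lengthscale_km: float = 12.0
    conc_gp_sd: float = 2.0
    conc_gp_len_km: float = 10.0
    conc_alpha: float = 2.5
    conc_beta: float = 0.022
    conc_sigma2: float = 0.01
    conc_phi: float = 0.015
    conc_kappa: float = 1.0


_CELL_KM = 4.0  # grid cell side, km


def make_lattice_region(side: int, cells_per_muni: int, seed: int) -> RegionGraph:
    """Build a ``side`` x ``side`` rook-adjacency lattice of municipalities.

    Each municipality owns ``cells_per_muni`` grid cells laid out inside its
    block. Populations are log-uniform; provinces are contiguous square
    blocks whose most populous member is flagged capital (and given a
    population boost so capitals look like cities).
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    if cells_per_muni < 1:
        raise ValueError("cells_per_muni must be >= 1")
    rng = np.random.default_rng(seed)
    n = side * side
    m = math.ceil(math.sqrt(cells_per_muni))
    block_km = _CELL_KM * m

    centroids = np.empty((n, 2))
    cell_xy = []
    cell_muni = []
    for r in range(side):
        for c in range(side):
            i = r * side + c
            x0, y0 = c * block_km, r * block_km
            centroids[i] = (x0 + block_km / 2, y0 + block_km / 2)
            for k in range(cells_per_muni):
                cr, cc = divmod(k, m)
                cell_xy.append((x0 + (cc + 0.5) * _CELL_KM, y0 + (cr + 0.5) * _CELL_KM))
                cell_muni.append(i)

    adjacency: list[np.ndarray] = []
    for r in range(side):
        for c in range(side):
            nbrs = []
            if r > 0:
                nbrs.append((r - 1) * side + c)
            if r < side - 1:
                nbrs.append((r + 1) * side + c)
            if c > 0:
                nbrs.append(r * side + c - 1)
            if c < side - 1:
                nbrs.append(r * side + c + 1)
            adjacency.append(np.array(sorted(nbrs), dtype=np.int64))

    pop2001 = np.round(np.exp(rng.uniform(math.log(500.0), math.log(5e4), n))).astype(np.int64)

    block = max(1, math.ceil(side / 3))
    rows = np.arange(n) // side
    cols = np.arange(n) % side
    province_id = (rows // block) * math.ceil(side / block) + (cols // block)
    # relabel provinces 0..P-1
    _, province_id = np.unique(province_id, return_inverse=True)

    capital_flag = np.zeros(n, dtype=bool)
    for p in np.unique(province_id):
        members = np.flatnonzero(province_id == p)
        cap = members[np.argmax(pop2001[members])]
        capital_flag[cap] = True
        pop2001[cap] = int(round(pop2001[cap] * 4.0))

    pop2007 = np.round(pop2001 * rng.uniform(0.97, 1.08, n)).astype(np.int64)
    pop2007 = np.maximum(pop2007, 1)

    region = RegionGraph(
        populations_2001=pop2001,
        populations_2007=pop2007,
        adjacency=adjacency,
        centroids=centroids,
        province_id=province_id,
        capital_flag=capital_flag,
        cell_centroids=np.asarray(cell_xy),
        cell_muni=np.asarray(cell_muni, dtype=np.int64),
    )
    region.validate()
    return region


def _icar_draw(adjacency: list[np.ndarray], tau_v2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the proper ICAR realization on the sum-to-zero subspace.

    Uses the spectral pseudo-inverse of the graph Laplacian: components with
    zero eigenvalue (one per connected component) carry no variance.
    """
    n = len(adjacency)
    if tau_v2 == 0.0:
        return np.zeros(n)
    lap = np.zeros((n, n))
    for i, nbrs in enumerate(adjacency):
        lap[i, i] = len(nbrs)
        lap[i, nbrs] = -1.0
    vals, vecs = np.linalg.eigh(lap)
    keep = vals > 1e-9
    z = rng.standard_normal(keep.sum())
    v = vecs[:, keep] @ (z / np.sqrt(vals[keep]))
    return math.sqrt(tau_v2) * v


def _gp_draw(coords: np.ndarray, sd: float, length_km: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(len(coords))
    d = cdist(coords, coords)
    cov = sd**2 * np.exp(-0.5 * (d / length_km) ** 2)
    cov[np.diag_indices_from(cov)] += 1e-10 * max(sd**2, 1.0)
    return rng.multivariate_normal(np.zeros(len(coords)), cov, method="cholesky")


def simulate_truth(region: RegionGraph, config: TruthConfig, seed: int) -> GroundTruth:
    """Simulate ground-truth rates, exposure field, effects and commuting."""
    if config.tau_u2 < 0 or config.tau_v2 < 0 or config.effect_sd < 0:
        raise ValueError("variance parameters must be nonnegative")
    if config.conc_sigma2 < 0:
        raise ValueError("conc_sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    n = region.n_munis

    u = rng.normal(0.0, math.sqrt(config.tau_u2), n) if config.tau_u2 > 0 else np.zeros(n)
    v = _icar_draw(region.adjacency, config.tau_v2, rng)
    true_rates = np.exp(config.baseline_log_rate + u + v)

    true_effects = rng.normal(config.effect_mean, config.effect_sd, n)

    # deterministic-model field z: smooth background + bumps centred on capitals
    cells = region.cell_centroids
    caps = region.centroids[region.capital_flag]
    d_cap = cdist(cells, caps)
    z = config.conc_base + config.conc_amp * np.exp(
        -0.5 * (d_cap / config.conc_lengthscale_km) ** 2
    ).sum(axis=1)
    z = z + _gp_draw(cells, config.conc_gp_sd, config.conc_gp_len_km, rng)

    # true log field = affine calibration of z + correlated residual, matching
    # the kriging likelihood exactly
    log_field = config.conc_alpha + config.conc_beta * z
    if config.conc_sigma2 > 0:
        d_cc = cdist(cells, cells)
        cov = config.conc_sigma2 * correlation(d_cc, config.conc_phi, config.conc_kappa)
        cov[np.diag_indices_from(cov)] += 1e-10
        log_field = log_field + rng.multivariate_normal(
            np.zeros(len(cells)), cov, method="cholesky"
        )
    field_cells = np.exp(log_field)
    field_munis = np.array(
        [field_cells[region.cell_muni == i].mean() for i in range(n)]
    )

    # gravity commuting with capital boost; vanishes as decay -> 0
    d = cdist(region.centroids, region.centroids)
    pop_scale = float(np.median(region.populations_2001))
    with np.errstate(divide="ignore"):
        w = (region.populations_2001 / pop_scale) ** config.gravity_gamma * np.exp(
            -d / max(config.gravity_decay_km, 1e-300)
        )
    w = w * np.where(region.capital_flag, config.capital_boost, 1.0)[None, :]
    np.fill_diagonal(w, 0.0)
    frac = np.where(
        region.capital_flag,
        rng.uniform(*config.capital_commute_frac_range, n),
        rng.uniform(*config.commute_frac_range, n),
    )
    denom = np.maximum(w.sum(axis=1), 1.0)
    p = frac[:, None] * w / denom[:, None]
    totals = p.sum(axis=1)
    over = totals > config.p_max
    if np.any(over):
        p[over] *= (config.p_max / totals[over])[:, None]

    return GroundTruth(
        true_rates=true_rates,
        true_field_cells=field_cells,
        true_field_munis=field_munis,
        true_effects=true_effects,
        true_commuting_probs=p,
        cell_z=z,
        conc_params={
            "alpha": config.conc_alpha,
            "beta": config.conc_beta,
            "sigma2": config.conc_sigma2,
            "phi": config.conc_phi,
            "kappa": config.conc_kappa,
        },
    )


def observe_study(
    truth: GroundTruth,
    region: RegionGraph,
    n_monitors: int,
    monitor_noise_sd: float,
    seed: int,
    effect_se_range: tuple[float, float] = (0.0003, 0.0006),
) -> SyntheticStudy:
    """Generate observed data from the truth.

    Deaths are Poisson with five person-years per resident; commuting counts
    are binomial; monitor log values carry additive normal noise around the
    true log field; grid predictions are the deterministic ``z`` values.
    Capital municipalities double as the "known cities" with noisy effect
    estimates and standard errors.
    """
    if n_monitors > region.n_cells:
        raise ValueError("n_monitors exceeds number of grid cells")
    if monitor_noise_sd < 0:
        raise ValueError("monitor_noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n = region.n_munis

    deaths = rng.poisson(5.0 * region.populations_2001 * truth.true_rates)

    od = rng.binomial(region.populations_2001[:, None], truth.true_commuting_probs)
    np.fill_diagonal(od, 0)
    for i in range(n):  # enforce row-sum <= population (essentially never fires)
        while od[i].sum() > region.populations_2001[i]:
            od[i] = rng.binomial(region.populations_2001[i], truth.true_commuting_probs[i])
            od[i, i] = 0

    monitor_cells = rng.choice(region.n_cells, size=n_monitors, replace=False)
    log_obs = np.log(truth.true_field_cells[monitor_cells])
    if monitor_noise_sd > 0:
        log_obs = log_obs + rng.normal(0.0, monitor_noise_sd, n_monitors)
    monitor_values = np.exp(log_obs)

    cap_ids = np.flatnonzero(region.capital_flag)
    ses = rng.uniform(*effect_se_range, len(cap_ids))
    estimates = rng.normal(truth.true_effects[cap_ids], ses)

    return SyntheticStudy(
        region=region,
        deaths_5yr=deaths,
        od_counts=od.astype(np.int64),
        monitor_cells=monitor_cells,
        monitor_values=monitor_values,
        grid_z=truth.cell_z,
        city_effect_ids=cap_ids,
        city_effect_estimates=estimates,
        city_effect_ses=ses,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# plain-CSV writers / readers (the synthetic_region dialect)

def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region = study.region
    n = region.n_munis

    pd.DataFrame(
        {
            "municipality_id": np.arange(n),
            "province_id": region.province_id,
            "capital": region.capital_flag.astype(int),
            "pop2001": region.populations_2001,
            "pop2007": region.populations_2007,
            "deaths5yr": study.deaths_5yr,
            "centroid_x_km": region.centroids[:, 0],
            "centroid_y_km": region.centroids[:, 1],
        }
    ).to_csv(out / "municipalities.csv", index=False)

    edges = [(i, j) for i in range(n) for j in region.adjacency[i] if i < j]
    pd.DataFrame(edges, columns=["municipality_i", "municipality_j"]).to_csv(
        out / "adjacency.csv", index=False
    )

    oi, dj = np.nonzero(study.od_counts)
    pd.DataFrame(
        {"origin": oi, "destination": dj, "count": study.od_counts[oi, dj]}
    ).to_csv(out / "od.csv", index=False)

    pd.DataFrame(
        {
            "monitor_id": np.arange(len(study.monitor_cells)),
            "cell_id": study.monitor_cells,
            "x_km": region.cell_centroids[study.monitor_cells, 0],
            "y_km": region.cell_centroids[study.monitor_cells, 1],
            "pm10": study.monitor_values,
        }
    ).to_csv(out / "monitors.csv", index=False)

    pd.DataFrame(
        {
            "cell_id": np.arange(region.n_cells),
            "municipality_id": region.cell_muni,
            "x_km": region.cell_centroids[:, 0],
            "y_km": region.cell_centroids[:, 1],
            "z_pred": study.grid_z,
        }
    ).to_csv(out / "grid.csv", index=False)

    pd.DataFrame(
        {
            "city_id": study.city_effect_ids,
            "log_rr_per_ug": study.city_effect_estimates,
            "se": study.city_effect_ses,
        }
    ).to_csv(out / "city_effects.csv", index=False)

    truth = study.truth
    pd.DataFrame(
        {
            "municipality_id": np.arange(n),
            "true_rate": truth.true_rates,
            "true_pm10": truth.true_field_munis,
            "true_beta": truth.true_effects,
        }
    ).to_csv(out / "truth.csv", index=False)


def read_region(in_dir: str | Path) -> tuple[RegionGraph, np.ndarray]:
    """Read municipalities + adjacency (+ grid if present); returns (region, deaths)."""
    in_dir = Path(in_dir)
    munis = pd.read_csv(in_dir / "municipalities.csv").sort_values("municipality_id")
    n = len(munis)
    edges = pd.read_csv(in_dir / "adjacency.csv")
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges.itertuples(index=False):
        nbrs[i].add(int(j))
        nbrs[j].add(int(i))
    grid_path = in_dir / "grid.csv"
    if grid_path.exists():
        grid = pd.read_csv(grid_path).sort_values("cell_id")
        cell_xy = grid[["x_km", "y_km"]].to_numpy()
        cell_muni = grid["municipality_id"].to_numpy(dtype=np.int64)
    else:
        cell_xy = munis[["centroid_x_km", "centroid_y_km"]].to_numpy()
        cell_muni = np.arange(n, dtype=np.int64)
    region = RegionGraph(
        populations_2001=munis["pop2001"].to_numpy(dtype=np.int64),
        populations_2007=munis["pop2007"].to_numpy(dtype=np.int64),
        adjacency=[np.array(sorted(s), dtype=np.int64) for s in nbrs],
        centroids=munis[["centroid_x_km", "centroid_y_km"]].to_numpy(),
        province_id=munis["province_id"].to_numpy(dtype=np.int64),
        capital_flag=munis["capital"].to_numpy(dtype=bool),
        cell_centroids=cell_xy,
        cell_muni=cell_muni,
    )
    return region, munis["deaths5yr"].to_numpy(dtype=np.int64)


def read_od_counts(in_dir: str | Path, n_munis: int) -> np.ndarray:
    od = pd.read_csv(Path(in_dir) / "od.csv")
    counts = np.zeros((n_munis, n_munis), dtype=np.int64)
    counts[od["origin"].to_numpy(), od["destination"].to_numpy()] = od["count"].to_numpy()
    np.fill_diagonal(counts, 0)
    return counts


def read_monitors(in_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(in_dir) / "monitors.csv").sort_values("monitor_id")


def read_grid(in_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(in_dir) / "grid.csv").sort_values("cell_id")


def read_city_effects(in_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(in_dir) / "city_effects.csv")
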