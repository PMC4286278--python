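"""Monte Carlo propagation of all input posteriors into impact draws.

Consumes draw-aligned posterior matrices row by row (never re-sampling
across rows, so between-municipality correlation carried by the joint
posteriors is preserved), samples one commuting-flow tensor and one set of
Poisson death counts per iteration, evaluates every reduction scenario on
those shared counts, and summarizes the resulting impact distributions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import impact as _impact
from .commuting import CommutingPosterior, FlowDraws, sample_flows

__all__ = [
    "McConfig",
    "ImpactDraws",
    "run_monte_carlo",
    "run_static",
    "summarize",
    "report_tables",
]


@dataclasses.dataclass
class McConfig:
    seed: int
    n_draws: int = 1000
    scenarios: tuple[str, ...] = ("RS0", "RS1", "RS2", "RS3")
    share: float = 1.0 / 3.0
    truncation: str = "term"
    expected_counts: bool = False

    def validate(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if not self.scenarios:
            raise ValueError("at least one scenario required")


@dataclasses.dataclass
class ImpactDraws:
    A: np.ndarray  # (n_draws, n_munis)
    B: np.ndarray
    C: np.ndarray

    @property
    def ad_ab(self) -> np.ndarray:
        return self.A + self.B

    @property
    def ad_ac(self) -> np.ndarray:
        return self.A + self.C

    @property
    def n_draws(self) -> int:
        return self.A.shape[0]


def _check_aligned(name: str, arr: np.ndarray, n_draws: int, n_munis: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_munis:
        raise ValueError(f"{name} must be (n_draws, {n_munis}); got {arr.shape}")
    if arr.shape[0] < n_draws:
        raise ValueError(f"{name} has {arr.shape[0]} draws; need {n_draws}")
    return arr[:n_draws]


def run_monte_carlo(
    rate_draws: np.ndarray,
    conc_draws: np.ndarray,
    effect_draws: np.ndarray,
    posterior: CommutingPosterior | None,
    pop_2007: np.ndarray,
    config: McConfig,
    flow_draws: FlowDraws | None = None,
) -> dict[str, ImpactDraws]:
    """Propagate input draws through the attributable-death calculus.

    Per draw d: one flow tensor realization and one pair of Poisson count
    samples (static deaths, commuter deaths) are drawn, then every scenario
    is evaluated on those same counts. The master seed spawns independent
    substreams for flows and for counts.
    """
    config.validate()
    pop = np.asarray(pop_2007)
    n = len(pop)
    rates = _check_aligned("rate_draws", rate_draws, config.n_draws, n)
    conc = _check_aligned("conc_draws", conc_draws, config.n_draws, n)
    eff = _check_aligned("effect_draws", effect_draws, config.n_draws, n)

    ss = np.random.SeedSequence(config.seed)
    flows_ss, counts_ss = ss.spawn(2)
    if flow_draws is None:
        if posterior is None:
            raise ValueError("either a commuting posterior or flow draws is required")
        flow_draws = sample_flows(posterior, pop, config.n_draws, flows_ss)
    if flow_draws.n_draws < config.n_draws:
        raise ValueError("flow draws fewer than n_draws")

    counts_rng = np.random.default_rng(counts_ss)
    out = {
        s: ImpactDraws(
            A=np.empty((config.n_draws, n)),
            B=np.empty((config.n_draws, n)),
            C=np.empty((config.n_draws, n)),
        )
        for s in config.scenarios
    }
    for d in range(config.n_draws):
        y_s, y_c = _impact.sample_death_counts(
            rates[d],
            flow_draws.draws[d],
            pop,
            config.share,
            counts_rng,
            config.expected_counts,
        )
        for s in config.scenarios:
            a, b, c = _impact.compute_ABC_from_counts(
                y_s, y_c, eff[d], conc[d], s, config.truncation
            )
            out[s].A[d], out[s].B[d], out[s].C[d] = a, b, c
    return out


def run_static(
    rate_draws: np.ndarray,
    conc_draws: np.ndarray,
    effect_draws: np.ndarray,
    pop_2007: np.ndarray,
    config: McConfig,
) -> dict[str, np.ndarray]:
    """Static (no-commuting) pipeline: AD = y - y/exp(beta (x - x0) I).

    An independent implementation of the commuting-free formula used as the
    reference in the zero-commuting equivalence check. Death counts use the
    same substream protocol as :func:`run_monte_carlo` (flows substream
    first, counts second), so in expected-counts mode the two pipelines are
    comparable draw by draw.
    """
    config.validate()
    pop = np.asarray(pop_2007, dtype=float)
    n = len(pop)
    rates = _check_aligned("rate_draws", rate_draws, config.n_draws, n)
    conc = _check_aligned("conc_draws", conc_draws, config.n_draws, n)
    eff = _check_aligned("effect_draws", effect_draws, config.n_draws, n)
    ss = np.random.SeedSequence(config.seed)
    _, counts_ss = ss.spawn(2)
    rng = np.random.default_rng(counts_ss)
    out: dict[str, np.ndarray] = {s: np.empty((config.n_draws, n)) for s in config.scenarios}
    for d in range(config.n_draws):
        mu = pop * rates[d]
        y = mu if config.expected_counts else rng.poisson(mu).astype(float)
        for s in config.scenarios:
            x0 = _impact.scenario_threshold(conc[d], s)
            out[s][d] = _impact.attributable_static(y, eff[d], conc[d], x0)
    return out


def summarize(
    draws: ImpactDraws,
    populations: np.ndarray,
    labels: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Group-level posterior summaries (sum municipalities within group per
    draw, then summarize across draws).

    ``labels`` assigns each municipality to a group (default: one group per
    municipality). Percentiles use linear interpolation between order
    statistics.
    """
    if draws.n_draws < 10:
        raise ValueError("need at least 10 draws for percentile stability")
    pop = np.asarray(populations, dtype=float)
    n = draws.A.shape[1]
    if labels is None:
        labels = np.arange(n)
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must match municipalities")
    rows = []
    for g in pd.unique(labels):
        members = np.flatnonzero(labels == g)
        if len(members) == 0:
            raise ValueError(f"empty group {g!r}")
        ab = draws.ad_ab[:, members].sum(axis=1)
        ac = draws.ad_ac[:, members].sum(axis=1)
        b = draws.B[:, members].sum(axis=1)
        c = draws.C[:, members].sum(axis=1)
        gpop = pop[members].sum()
        lo, med, hi = np.percentile(ab, [10, 50, 90])
        lo_c, med_c, hi_c = np.percentile(ac, [10, 50, 90])
        rows.append(
            {
                "group": g,
                "n_munis": len(members),
                "population": gpop,
                "ad_ab_median": med,
                "ad_ab_cri10": lo,
                "ad_ab_cri90": hi,
                "ad_ac_median": med_c,
                "ad_ac_cri10": lo_c,
                "ad_ac_cri90": hi_c,
                "pr_positive": float(np.mean(ab > 0)),
                "pr_export_gt_import": float(np.mean(c > b)),
                "acr_median": float(np.median(_impact.acr(ab, gpop))),
                "b_median": float(np.median(b)),
                "c_median": float(np.median(c)),
            }
        )
    return pd.DataFrame(rows)


def report_tables(
    results: dict[str, ImpactDraws],
    province_id: np.ndarray,
    capital_flag: np.ndarray,
    populations: np.ndarray,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Report tables: province impacts, ACRs, capital export/import balance,
    and the per-municipality export/import log ratio.

    The Total row summarizes the per-draw regional sum (never a column sum
    of medians).
    """
    province_id = np.asarray(province_id)
    capital_flag = np.asarray(capital_flag, dtype=bool)
    pop = np.asarray(populations, dtype=float)
    tables: dict[str, pd.DataFrame] = {}

    prov_rows = []
    for s, draws in results.items():
        by_prov = summarize(draws, pop, province_id)
        by_prov.insert(0, "scenario", s)
        total = summarize(draws, pop, np.zeros(len(pop), dtype=int))
        total["group"] = "Total"
        total.insert(0, "scenario", s)
        prov_rows.append(pd.concat([by_prov, total], ignore_index=True))
    tables["province"] = pd.concat(prov_rows, ignore_index=True).rename(
        columns={"group": "province"}
    )

    acr_rows = []
    for s in [s for s in ("RS0", "RS1") if s in results]:
        draws = results[s]
        by_prov = summarize(draws, pop, province_id).set_index("group")
        for p in np.unique(province_id):
            cap = np.flatnonzero((province_id == p) & capital_flag)
            cap_ab = draws.ad_ab[:, cap].sum(axis=1)
            acr_rows.append(
                {
                    "scenario": s,
                    "province": p,
                    "population_province": pop[province_id == p].sum(),
                    "population_capital": pop[cap].sum(),
                    "acr_province": by_prov.loc[p, "acr_median"],
                    "acr_capital": float(
                        np.median(_impact.acr(cap_ab, pop[cap].sum()))
                    ),
                }
            )
        total = summarize(draws, pop, np.zeros(len(pop), dtype=int))
        caps = np.flatnonzero(capital_flag)
        caps_ab = draws.ad_ab[:, caps].sum(axis=1)
        acr_rows.append(
            {
                "scenario": s,
                "province": "Total",
                "population_province": pop.sum(),
                "population_capital": pop[caps].sum(),
                "acr_province": float(total["acr_median"].iloc[0]),
                "acr_capital": float(np.median(_impact.acr(caps_ab, pop[caps].sum()))),
            }
        )
    if acr_rows:
        tables["acr"] = pd.DataFrame(acr_rows)

    if "RS0" in results:
        draws = results["RS0"]
        caps = np.flatnonzero(capital_flag)
        cap_rows = []
        for i in caps:
            ab, ac = draws.ad_ab[:, i], draws.ad_ac[:, i]
            cap_rows.append(
                {
                    "municipality_id": i,
                    "province": province_id[i],
                    "ad_ab_median": float(np.median(ab)),
                    "ad_ab_cri10": float(np.percentile(ab, 10)),
                    "ad_ab_cri90": float(np.percentile(ab, 90)),
                    "ad_ac_median": float(np.median(ac)),
                    "ad_ac_cri10": float(np.percentile(ac, 10)),
                    "ad_ac_cri90": float(np.percentile(ac, 90)),
                    "pr_export_gt_import": float(
                        np.mean(draws.C[:, i] > draws.B[:, i])
                    ),
                }
            )
        tables["capitals"] = pd.DataFrame(cap_rows)

        b_med = np.median(draws.B, axis=0)
        c_med = np.median(draws.C, axis=0)
        ratio = _impact.export_import_log_ratio(c_med, b_med)
        flag = np.select(
            [
                (c_med == 0) & (b_med == 0),
                (c_med > 0) & (b_med == 0),
                (c_med == 0) & (b_med > 0),
            ],
            ["undefined", "export_only", "import_only"],
            default="finite",
        )
        tables["log_ratio"] = pd.DataFrame(
            {
                "municipality_id": np.arange(len(pop)),
                "b_median": b_med,
                "c_median": c_med,
                "log_ratio": ratio,
                "flag": flag,
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"table_{name}.csv", index=False)
    return tables
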