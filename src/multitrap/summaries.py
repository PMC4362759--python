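"""Replicate aggregation into the two headline statistics.

A scenario's results are summarised as (a) the distribution over traps of
the number of captures per trap — the quantity that tells a manager how
much capture capacity a site actually needs — and (b) the proportion of
the exposed population (residents plus any immigrants introduced) that was
removed.  Point estimates are arithmetic means over replicates; empirical
spreads (standard deviation and 2.5/97.5 percentiles across replicates)
are reported alongside.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .engine import ReplicateResult, replicate_rng, simulate_replicate

__all__ = [
    "trap_capture_distribution",
    "population_capture_proportion",
    "proportion_traps_at_least",
    "density_sweep",
]


def _check_results(results: Sequence[ReplicateResult]) -> None:
    if len(results) == 0:
        raise ValueError("at least one replicate result is required")


def trap_capture_distribution(
    results: Sequence[ReplicateResult], capacity: Optional[int] = None
) -> pd.DataFrame:
    """Mean proportion of traps with exactly k captures, k = 0..capacity.

    One row per k with columns ``k``, ``proportion`` (mean over replicates
    of #traps with k captures / #traps), ``sd``, ``q2.5``, ``q97.5`` and
    ``tail`` (mean proportion of traps with >= k captures).  Rows sum to 1
    by construction.
    """
    _check_results(results)
    if capacity is None:
        capacity = results[0].capacity
    per_rep = np.stack(
        [
            np.bincount(r.trap_counts, minlength=capacity + 1)[: capacity + 1]
            / len(r.trap_counts)
            for r in results
        ]
    )  # (replicates, capacity + 1)
    tail = per_rep[:, ::-1].cumsum(axis=1)[:, ::-1]
    return pd.DataFrame(
        {
            "k": np.arange(capacity + 1),
            "proportion": per_rep.mean(axis=0),
            "sd": per_rep.std(axis=0, ddof=1) if len(results) > 1 else 0.0,
            "q2.5": np.percentile(per_rep, 2.5, axis=0),
            "q97.5": np.percentile(per_rep, 97.5, axis=0),
            "tail": tail.mean(axis=0),
        }
    )


def proportion_traps_at_least(
    results: Sequence[ReplicateResult], k: int = 1
) -> float:
    """Mean proportion of traps with at least ``k`` captures."""
    _check_results(results)
    return float(
        np.mean([np.mean(r.trap_counts >= k) for r in results])
    )


def population_capture_proportion(
    results: Sequence[ReplicateResult],
) -> dict[str, float]:
    """Mean proportion of the exposed population captured, with spread.

    The denominator of each replicate is residents plus all immigrants
    introduced during the run.
    """
    _check_results(results)
    props = np.array([r.proportion_captured for r in results])
    return {
        "mean": float(props.mean()),
        "sd": float(props.std(ddof=1)) if len(props) > 1 else 0.0,
        "q2.5": float(np.percentile(props, 2.5)),
        "q97.5": float(np.percentile(props, 97.5)),
    }


def summarise_scenario(
    cfg: ScenarioConfig, results: Sequence[ReplicateResult]
) -> pd.DataFrame:
    """Tidy long-format summary of one scenario.

    Columns: species, density, capacity, statistic, k, value.  Statistics
    are the per-k trap proportions (``traps_k`` / ``traps_k_tail``) and the
    population kill (``population_captured``), each with mean and spread
    rows (``stat`` one of mean/sd/q2.5/q97.5).
    """
    dist = trap_capture_distribution(results, cfg.capacity)
    pop = population_capture_proportion(results)
    rows = []
    meta = {
        "species": cfg.species or "",
        "density": cfg.density,
        "capacity": cfg.capacity,
    }
    for _, r in dist.iterrows():
        for stat in ("proportion", "sd", "q2.5", "q97.5", "tail"):
            rows.append(
                {
                    **meta,
                    "statistic": "traps_k" if stat != "tail" else "traps_k_tail",
                    "k": int(r["k"]),
                    "stat": "mean" if stat in ("proportion", "tail") else stat,
                    "value": float(r[stat]),
                }
            )
    for stat, value in pop.items():
        rows.append(
            {
                **meta,
                "statistic": "population_captured",
                "k": -1,
                "stat": stat,
                "value": value,
            }
        )
    return pd.DataFrame(rows)


def density_sweep(
    cfg: ScenarioConfig,
    densities: Sequence[float],
    capacities: Sequence[int],
    progress: bool = False,
) -> pd.DataFrame:
    """Run every (density, capacity) cell and stack the tidy summaries.

    Each cell draws its replicate streams from ``(seed, density index,
    capacity index, replicate)``, so adding densities or capacities never
    perturbs existing cells.
    """
    if len(densities) == 0 or len(capacities) == 0:
        raise ValueError("densities and capacities must be non-empty")
    frames = []
    cells = [
        (di, d, ci, c)
        for di, d in enumerate(densities)
        for ci, c in enumerate(capacities)
    ]
    if progress:
        from tqdm import tqdm

        cells = tqdm(cells, desc="sweep cells")
    for di, d, ci, c in cells:
        cell_cfg = cfg.replace(density=float(d), capacity=int(c))
        results = [
            simulate_replicate(
                cell_cfg, replicate_rng(cfg.seed, r, di, ci)
            )
            for r in range(cfg.replicates)
        ]
        frames.append(summarise_scenario(cell_cfg, results))
    return pd.concat(frames, ignore_index=True)
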