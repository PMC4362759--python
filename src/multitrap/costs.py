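"""Cost comparison of trap deployment strategies.

Compares deploying ``n`` single-capture traps at every site against one
multiple-capture trap per site.  Costs per hectare split into a hardware
component (trap price) and a labour component (set-up plus periodic
checking time, converted to currency through a daily contract rate).  The
formula is deliberately parameterised — number of checks per period,
labour-to-price exchange rate and working minutes per day are explicit
inputs — because published per-hectare figures rarely state them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TrapCostSpec",
    "LabourSpec",
    "CostBreakdown",
    "cost_per_hectare",
    "strategy_compare",
    "trap_cost_preset",
    "TRAP_COST_PRESETS",
]


@dataclass(frozen=True)
class TrapCostSpec:
    """Price and handling times for one trap model.

    ``traps_per_site`` is how many of this trap are set at each site (one
    for a multiple-capture trap; possibly several for single-capture
    traps).
    """

    price: float  # currency per trap
    setup_time: float  # minutes per trap
    check_time: float  # minutes per trap per check
    traps_per_site: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.price < 0 or self.setup_time < 0 or self.check_time < 0:
            raise ValueError("price and times must be non-negative")
        if self.traps_per_site < 1:
            raise ValueError("traps_per_site must be >= 1")


@dataclass(frozen=True)
class LabourSpec:
    """Labour costing: a daily contract rate spread over working minutes.

    ``exchange_rate`` converts the labour currency into the trap-price
    currency (1 if both are quoted in the same currency).
    """

    daily_rate: float = 300.0  # NZ$ contract rate per field day
    minutes_per_day: float = 480.0
    n_checks: int = 1  # trap checks per trapping period
    exchange_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.daily_rate <= 0 or self.minutes_per_day <= 0:
            raise ValueError("daily_rate and minutes_per_day must be positive")
        if self.n_checks < 0:
            raise ValueError("n_checks must be non-negative")
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be positive")


@dataclass(frozen=True)
class CostBreakdown:
    """Itemised per-hectare cost; hardware + labour == total exactly."""

    hardware: float
    labour: float

    @property
    def total(self) -> float:
        return self.hardware + self.labour


#: Indicative trap models: price (US$), set-up and checking/reset times
#: (minutes), from vendor quotes and field-staff estimates.
TRAP_COST_PRESETS: dict[str, TrapCostSpec] = {
    "sentinel": TrapCostSpec(24.00, 5, 2, name="sentinel"),
    "a12": TrapCostSpec(140.00, 5, 3, name="a12"),
    "a24": TrapCostSpec(140.00, 5, 3, name="a24"),
    "victor-snapback": TrapCostSpec(6.30, 4, 2, name="victor-snapback"),
    "doc150": TrapCostSpec(38.00, 3, 3, name="doc150"),
}


def trap_cost_preset(name: str, traps_per_site: int = 1) -> TrapCostSpec:
    """A named trap-cost preset, optionally with several traps per site."""
    key = name.lower()
    if key not in TRAP_COST_PRESETS:
        raise KeyError(
            f"unknown trap model {name!r}; available: {sorted(TRAP_COST_PRESETS)}"
        )
    base = TRAP_COST_PRESETS[key]
    return TrapCostSpec(
        base.price, base.setup_time, base.check_time, traps_per_site, base.name
    )


def cost_per_hectare(
    trap: TrapCostSpec, labour: LabourSpec, n_sites: int, area: float
) -> CostBreakdown:
    """Per-hectare cost of equipping and servicing ``n_sites`` sites.

    hardware = price * traps_per_site * n_sites / area
    labour   = (setup + n_checks * check) minutes per trap, across all
               traps, valued at the daily rate and exchange rate, / area
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    n_traps = trap.traps_per_site * n_sites
    hardware = trap.price * n_traps / area
    minutes = (trap.setup_time + labour.n_checks * trap.check_time) * n_traps
    labour_cost = (
        minutes / labour.minutes_per_day * labour.daily_rate * labour.exchange_rate
    ) / area
    return CostBreakdown(hardware=hardware, labour=labour_cost)


def strategy_compare(
    single: TrapCostSpec,
    multi: TrapCostSpec,
    labour: LabourSpec,
    n_sites: int,
    area: float,
    max_traps_per_site: int,
) -> pd.DataFrame:
    """Totals for 1..max single traps per site against one multi trap.

    Returns a tidy table with one row per configuration: strategy, trap
    model, traps per site, hardware, labour and total cost per hectare.
    """
    if max_traps_per_site < 1:
        raise ValueError("max_traps_per_site must be >= 1")
    rows = []
    for n in range(1, max_traps_per_site + 1):
        spec = TrapCostSpec(
            single.price, single.setup_time, single.check_time, n, single.name
        )
        bd = cost_per_hectare(spec, labour, n_sites, area)
        rows.append(
            {
                "strategy": "single",
                "trap": single.name or "single",
                "traps_per_site": n,
                "hardware_per_ha": bd.hardware,
                "labour_per_ha": bd.labour,
                "total_per_ha": bd.total,
            }
        )
    bd = cost_per_hectare(multi, labour, n_sites, area)
    rows.append(
        {
            "strategy": "multi",
            "trap": multi.name or "multi",
            "traps_per_site": multi.traps_per_site,
            "hardware_per_ha": bd.hardware,
            "labour_per_ha": bd.labour,
            "total_per_ha": bd.total,
        }
    )
    return pd.DataFrame(rows)
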