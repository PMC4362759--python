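"""Reinvasion of the trapped block during the trapping period.

Where enabled (rats in the shipped presets), a population equal in size to
the initial one arrives over the trapping period: nightly arrivals equal
the initial density divided by the number of nights, with the fractional
remainder carried deterministically so the schedule sums exactly.

Arriving animals settle with a perimeter-to-centre gradient: the buffered
rectangle is split into three nested rectangular frames of equal step
width ("equidistant steps"), and by default 60%, 30% and 10% of immigrants
take home ranges in the outer, middle and inner zone respectively.  Within
its zone an immigrant's home-range centre is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import LayoutSpec
from .population import ORIGIN_IMMIGRANT, STATUS_AT_LARGE, PopulationState

__all__ = [
    "ImmigrationSpec",
    "immigrant_schedule",
    "assign_zones",
    "place_immigrants",
    "zone_of_points",
]


@dataclass(frozen=True)
class ImmigrationSpec:
    """Configuration of the immigration process.

    Parameters
    ----------
    total_immigrants : int or None
        Animals arriving over the whole period.  ``None`` means "equal to
        the initial resident population", the default reinvasion pressure.
    zone_weights : sequence of float
        Proportion of immigrants settling in each zone, outer to inner;
        must be non-negative and sum to 1.
    """

    total_immigrants: Optional[int] = None
    zone_weights: Sequence[float] = (0.6, 0.3, 0.1)

    def __post_init__(self) -> None:
        w = np.asarray(self.zone_weights, dtype=float)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("zone_weights must be a non-empty 1-D sequence")
        if np.any(w < 0):
            raise ValueError("zone_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"zone_weights must sum to 1, got {w.sum()}")
        if self.total_immigrants is not None and self.total_immigrants < 0:
            raise ValueError("total_immigrants must be non-negative")
        object.__setattr__(self, "zone_weights", tuple(float(x) for x in w))

    @property
    def n_zones(self) -> int:
        return len(self.zone_weights)


def immigrant_schedule(total: int, nights: int) -> np.ndarray:
    """Per-night arrival counts summing exactly to ``total``.

    The nightly quota is ``total / nights``; the fractional remainder is
    carried from night to night (night ``k`` receives
    ``round(k * total / nights) - round((k - 1) * total / nights)``), so
    counts differ by at most one and the schedule is deterministic.
    """
    if nights < 1:
        raise ValueError("nights must be >= 1")
    if total < 0:
        raise ValueError("total must be non-negative")
    cum = np.rint(total * np.arange(nights + 1) / nights).astype(np.int64)
    return np.diff(cum)


def assign_zones(
    n: int, spec: ImmigrationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw a zone label (0 = outer) for each of ``n`` immigrants."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(spec.n_zones, size=n, p=np.asarray(spec.zone_weights))


def _zone_step(layout: LayoutSpec, n_zones: int) -> float:
    """Width of one zone step: the half-width of the smaller dimension
    divided by the number of zones."""
    w, h = layout.extent
    return min(w, h) / 2.0 / n_zones


def zone_of_points(points: np.ndarray, layout: LayoutSpec, n_zones: int) -> np.ndarray:
    """Zone index of each point: 0 at the perimeter up to n_zones - 1 at
    the centre, by distance to the nearest edge in units of the step."""
    w, h = layout.extent
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    edge_dist = np.minimum.reduce(
        [pts[:, 0], w - pts[:, 0], pts[:, 1], h - pts[:, 1]]
    )
    step = _zone_step(layout, n_zones)
    return np.minimum(np.floor(edge_dist / step).astype(np.int64), n_zones - 1)


def place_immigrants(
    zones: np.ndarray,
    layout: LayoutSpec,
    rng: np.random.Generator,
    n_zones: int = 3,
) -> np.ndarray:
    """Sample a uniform home-range centre within each immigrant's zone.

    Uses rejection sampling from the buffered rectangle, which is exact and
    cheap because every zone holds a non-trivial share of the area.
    """
    zones = np.asarray(zones, dtype=np.int64)
    if len(zones) and zones.max() >= n_zones:
        raise ValueError("zone label exceeds n_zones - 1")
    w, h = layout.extent
    centres = np.empty((len(zones), 2), dtype=float)
    pending = np.arange(len(zones))
    while len(pending):
        draws = rng.uniform(low=[0.0, 0.0], high=[w, h], size=(len(pending), 2))
        got = zone_of_points(draws, layout, n_zones) == zones[pending]
        centres[pending[got]] = draws[got]
        pending = pending[~got]
    return centres


def make_immigrants(
    n: int, spec: ImmigrationSpec, layout: LayoutSpec, rng: np.random.Generator
) -> PopulationState:
    """Zone-assign and place ``n`` immigrants, all at large."""
    zones = assign_zones(n, spec, rng)
    centres = place_immigrants(zones, layout, rng, n_zones=spec.n_zones)
    return PopulationState(
        centres=centres,
        status=np.full(n, STATUS_AT_LARGE, dtype=np.int8),
        origin=np.full(n, ORIGIN_IMMIGRANT, dtype=np.int8),
    )
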