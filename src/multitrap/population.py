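"""Animal populations: home-range centres, capture status and origin.

Animals hold circular home ranges whose centres are uniformly distributed
over the buffered rectangle and fixed for the whole trapping period.
Captured animals are removed from the population permanently (removal
trapping), never returning to at-large status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LayoutSpec

__all__ = ["PopulationState", "init_population", "STATUS_AT_LARGE", "STATUS_CAPTURED"]

STATUS_AT_LARGE = 0
STATUS_CAPTURED = 1

ORIGIN_RESIDENT = 0
ORIGIN_IMMIGRANT = 1


@dataclass
class PopulationState:
    """Centres plus per-animal status and origin labels.

    ``status`` is 0 (at large) or 1 (captured); ``origin`` is 0 (resident,
    present from night one) or 1 (immigrant, arriving during the period).
    """

    centres: np.ndarray  # (n, 2) metres
    status: np.ndarray  # int, STATUS_* codes
    origin: np.ndarray  # int, ORIGIN_* codes

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 2)
        self.status = np.asarray(self.status, dtype=np.int8)
        self.origin = np.asarray(self.origin, dtype=np.int8)
        if not (len(self.centres) == len(self.status) == len(self.origin)):
            raise ValueError("centres, status and origin must have equal length")

    @property
    def n_animals(self) -> int:
        return len(self.centres)

    @property
    def n_residents(self) -> int:
        return int(np.sum(self.origin == ORIGIN_RESIDENT))

    @property
    def n_immigrants(self) -> int:
        return int(np.sum(self.origin == ORIGIN_IMMIGRANT))

    @property
    def n_captured(self) -> int:
        return int(np.sum(self.status == STATUS_CAPTURED))

    @property
    def at_large(self) -> np.ndarray:
        return self.status == STATUS_AT_LARGE


def population_size(density: float, layout: LayoutSpec) -> int:
    """Number of residents: density times the nominal buffered area, rounded."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return int(round(density * layout.buffered_area))


def init_population(
    layout: LayoutSpec, density: float, rng: np.random.Generator
) -> PopulationState:
    """Place ``round(density * buffered_area)`` residents uniformly.

    Centres are uniform over the buffered rectangle (grid span plus buffer
    on all four sides), all animals start at large, all are residents.
    """
    n = population_size(density, layout)
    w, h = layout.extent
    centres = rng.uniform(low=[0.0, 0.0], high=[w, h], size=(n, 2))
    return PopulationState(
        centres=centres,
        status=np.zeros(n, dtype=np.int8),
        origin=np.zeros(n, dtype=np.int8),
    )
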