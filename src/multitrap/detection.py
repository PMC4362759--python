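"""Half-normal detection function and its parameters.

The nightly capture probability of an animal in a given trap declines with
the distance between the trap and the centre of the animal's (circular,
stationary) home range:

    P(d) = g0 * exp(-d**2 / (2 * sigma**2))

``g0`` is the capture probability for a trap sitting exactly at the
home-range centre, and ``sigma`` sets the spatial scale of the home range:
a radius of 2.45*sigma contains about 95% of the animal's activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectionParams", "capture_probability", "home_range_radius95"]

#: Multiplier of sigma giving the radius containing ~95% of activity for a
#: circular bivariate-normal utilisation distribution.
RADIUS95_MULTIPLIER = 2.45


@dataclass(frozen=True)
class DetectionParams:
    """Species-level parameters of the half-normal detection function.

    Parameters
    ----------
    g0 : float
        Nightly capture probability at the home-range centre, in (0, 1].
    sigma : float
        Home-range spatial scale in metres, > 0.
    """

    g0: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.g0 <= 1.0:
            raise ValueError(f"g0 must be in (0, 1], got {self.g0}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def capture_probability(d, params: DetectionParams):
    """Nightly capture probability at trap-to-centre distance ``d`` metres.

    Accepts a scalar or array of distances; negative distances are an error.
    The result is strictly decreasing in ``d`` and lies in (0, g0].
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("distance must be non-negative")
    p = params.g0 * np.exp(-(d**2) / (2.0 * params.sigma**2))
    return float(p) if p.ndim == 0 else p


def home_range_radius95(params: DetectionParams) -> float:
    """Radius (metres) within which the animal spends ~95% of its time."""
    return RADIUS95_MULTIPLIER * params.sigma
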