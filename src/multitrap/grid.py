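"""Trap-grid geometry: layouts, coordinates and per-trap capture capacity.

Traps sit on a regular grid of ``n_lines`` parallel lines with
``traps_per_line`` traps on each line.  The grid is surrounded on all four
sides by an untrapped buffer in which animals may still hold home ranges,
so that animals at the grid edge are not artificially clipped.  All
coordinates are metres on a continuous plane with the origin at the outer
corner of the buffered rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LayoutSpec", "TrapGrid", "build_trap_grid"]


@dataclass(frozen=True)
class LayoutSpec:
    """Geometry of a rectangular trapping grid plus its buffer.

    Parameters
    ----------
    trap_spacing : float
        Metres between adjacent traps along a line.
    line_spacing : float
        Metres between adjacent trap lines.
    traps_per_line, n_lines : int
        Grid dimensions; total sites = ``traps_per_line * n_lines``.
    buffer : float
        Width in metres of the untrapped margin on every side.
    buffered_area : float
        Nominal area in hectares over which animals are placed.  Kept as an
        explicit field (rather than recomputed from the spans) so that
        standard published layouts, whose rounded areas differ by a few
        percent from the exact grid-span arithmetic, reproduce their stated
        population sizes exactly.
    """

    trap_spacing: float
    line_spacing: float
    traps_per_line: int
    n_lines: int
    buffer: float
    buffered_area: float

    def __post_init__(self) -> None:
        if self.trap_spacing <= 0 or self.line_spacing <= 0:
            raise ValueError("trap and line spacings must be positive")
        if self.traps_per_line < 1 or self.n_lines < 1:
            raise ValueError("traps_per_line and n_lines must be >= 1")
        if self.buffer < 0:
            raise ValueError("buffer must be non-negative")
        if self.buffered_area <= 0:
            raise ValueError("buffered_area must be positive")

    @property
    def n_sites(self) -> int:
        return self.traps_per_line * self.n_lines

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in metres of the buffered rectangle.

        Width runs along trap lines, height across lines; the buffer is
        added on both sides of each dimension.
        """
        w = (self.traps_per_line - 1) * self.trap_spacing + 2 * self.buffer
        h = (self.n_lines - 1) * self.line_spacing + 2 * self.buffer
        return (w, h)

    @property
    def geometric_buffered_area_ha(self) -> float:
        """Area of the buffered rectangle from the spans, in hectares."""
        w, h = self.extent
        return w * h / 1e4


@dataclass
class TrapGrid:
    """Trap coordinates plus mutable per-trap capture state.

    ``remaining`` counts captures a trap can still make; a trap is
    ``active`` exactly while ``remaining > 0``.  Single-capture traps are
    the ``capacity == 1`` special case.
    """

    positions: np.ndarray  # (n_traps, 2) metres
    capacity: int
    remaining: np.ndarray = field(default=None)  # type: ignore[assignment]
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        n = len(self.positions)
        if self.remaining is None:
            self.remaining = np.full(n, self.capacity, dtype=np.int64)
        if self.active is None:
            self.active = self.remaining > 0

    @property
    def n_traps(self) -> int:
        return len(self.positions)

    @property
    def captures(self) -> np.ndarray:
        """Per-trap capture counts accumulated so far."""
        return self.capacity - self.remaining

    def record_capture(self, trap: int) -> None:
        """Decrement a trap's remaining capacity, deactivating it at zero."""
        if self.remaining[trap] <= 0:
            raise ValueError(f"trap {trap} is already saturated")
        self.remaining[trap] -= 1
        if self.remaining[trap] == 0:
            self.active[trap] = False

    def reset(self) -> None:
        self.remaining[:] = self.capacity
        self.active[:] = True


def build_trap_grid(layout: LayoutSpec, capacity: int) -> TrapGrid:
    """Lay out ``traps_per_line * n_lines`` traps inside the buffer.

    Trap (i, j) sits at ``(buffer + i * trap_spacing,
    buffer + j * line_spacing)``.  Every trap starts fully armed
    (``remaining == capacity``) and active.
    """
    xs = layout.buffer + layout.trap_spacing * np.arange(layout.traps_per_line)
    ys = layout.buffer + layout.line_spacing * np.arange(layout.n_lines)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    return TrapGrid(positions=positions, capacity=capacity)
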