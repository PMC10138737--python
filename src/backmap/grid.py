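"""Scalp stimulation grid geometry.

The mapping protocol stimulates a 5 x 8 grid of scalp sites spaced 1 cm apart
over one hemisphere: columns run medio-laterally from the midline (x = 0 cm)
to 4 cm lateral, rows run antero-posteriorly from 2 cm posterior to the vertex
(y = -2 cm) to 5 cm anterior (y = +5 cm).  All map metrics are expressed in
this centimetre frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "default_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the stimulation grid.

    ``z`` arrays indexed ``[row, col]`` pair with ``y_coords[row]`` and
    ``x_coords[col]``.  Coordinates must be strictly increasing.
    """

    n_cols: int = 5
    n_rows: int = 8
    spacing_cm: float = 1.0
    x_coords: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    y_coords: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if len(self.x_coords) != self.n_cols:
            raise ValueError(f"expected {self.n_cols} x coordinates, got {len(self.x_coords)}")
        if len(self.y_coords) != self.n_rows:
            raise ValueError(f"expected {self.n_rows} y coordinates, got {len(self.y_coords)}")
        if np.any(np.diff(self.x_coords) <= 0) or np.any(np.diff(self.y_coords) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_rows, n_cols)`` of site-indexed maps."""
        return (self.n_rows, self.n_cols)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` coordinate arrays of shape ``(n_rows, n_cols)`` in cm."""
        return np.meshgrid(np.asarray(self.x_coords), np.asarray(self.y_coords))

    def contains(self, x: float, y: float) -> bool:
        """True if the point (x, y) cm lies within the rectangular hull of the grid."""
        return (
            self.x_coords[0] <= x <= self.x_coords[-1]
            and self.y_coords[0] <= y <= self.y_coords[-1]
        )

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((x_min, x_max), (y_min, y_max)) in cm."""
        return (
            (self.x_coords[0], self.x_coords[-1]),
            (self.y_coords[0], self.y_coords[-1]),
        )


def default_grid() -> GridSpec:
    """The 5 x 8, 1-cm grid used throughout: midline to 4 cm lateral, -2 to +5 cm
    relative to the vertex (positive anterior)."""
    return GridSpec()
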