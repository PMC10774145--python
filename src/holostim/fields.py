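"""Discretized fields on the periodic space x orientation domain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from holostim.config import ModelConfig


def fold_orientation(delta_theta) -> np.ndarray:
    """Fold an orientation difference (degrees) into [0, 90].

    Orientation is 180-degree periodic, so a difference of 135 degrees is the
    same as 45 degrees and adding 180 degrees to either preference is a no-op.
    """
    d = np.abs(np.asarray(delta_theta, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


@dataclass
class FieldState:
    """Real-valued function sampled on the (x, y, theta) lattice.

    ``values[i, j, k]`` is the field at position ``(i * spacing, j * spacing)``
    and orientation level ``theta_levels[k]``.  The spatial domain is a
    periodic square of side ``domain_size``.
    """

    values: np.ndarray
    grid_spacing: float
    domain_size: float
    theta_levels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.theta_levels = np.asarray(self.theta_levels, dtype=float)
        n = int(round(self.domain_size / self.grid_spacing))
        if self.values.shape != (n, n, len(self.theta_levels)):
            raise ValueError(
                f"field shape {self.values.shape} inconsistent with grid "
                f"({n}, {n}, {len(self.theta_levels)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @classmethod
    def zeros(cls, config: ModelConfig) -> "FieldState":
        n = config.n_grid
        return cls(
            np.zeros((n, n, config.n_orientations)),
            config.grid_spacing,
            config.domain_size,
            config.orientation_levels,
        )

    @property
    def cell_area(self) -> float:
        """Area element of one spatial grid cell (um^2)."""
        return self.grid_spacing**2

    def integral(self) -> float:
        """Total mass: sum over nodes and orientation levels times cell area."""
        return float(self.values.sum() * self.cell_area)

    def axis_coords(self) -> np.ndarray:
        n = self.values.shape[0]
        return np.arange(n) * self.grid_spacing

    def copy_with(self, values: np.ndarray) -> "FieldState":
        return FieldState(values, self.grid_spacing, self.domain_size, self.theta_levels)

    def __add__(self, other: "FieldState") -> "FieldState":
        return self.copy_with(self.values + other.values)

    def __sub__(self, other: "FieldState") -> "FieldState":
        return self.copy_with(self.values - other.values)

    def __mul__(self, scalar: float) -> "FieldState":
        return self.copy_with(self.values * scalar)

    __rmul__ = __mul__


def periodic_distance_grid(config: ModelConfig) -> np.ndarray:
    """(n, n) matrix of distances from the origin node on the periodic square."""
    n = config.n_grid
    x = np.arange(n) * config.grid_spacing
    d = np.minimum(x, config.domain_size - x)
    return np.sqrt(d[:, None] ** 2 + d[None, :] ** 2)


def min_distance_grid(targets_xy: np.ndarray, config: ModelConfig) -> np.ndarray:
    """(n, n) matrix of minimal periodic distance from each node to any target."""
    n = config.n_grid
    xg = np.arange(n) * config.grid_spacing
    out = np.full((n, n), np.inf)
    for tx, ty in np.atleast_2d(targets_xy):
        dx = np.abs(xg - tx)
        dx = np.minimum(dx, config.domain_size - dx)
        dy = np.abs(xg - ty)
        dy = np.minimum(dy, config.domain_size - dy)
        out = np.minimum(out, np.sqrt(dx[:, None] ** 2 + dy[None, :] ** 2))
    return out
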