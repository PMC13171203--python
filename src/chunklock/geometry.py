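"""Toy sensor and source geometries on a single-sphere head model.

All positions are in metres, in a head-centred coordinate system with +z
pointing up through the vertex. The conductor is a homogeneous sphere;
magnetometers sit on a spherical cap above it and measure the field
component along their (radial) orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sphere",
    "SensorLayout",
    "SourceGrid",
    "toy_sensor_layout",
    "toy_source_grid",
    "head_source_grid",
]


@dataclass(frozen=True)
class Sphere:
    """Homogeneous spherical volume conductor."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.linalg.norm(points - self.center, axis=-1) < self.radius


@dataclass
class SensorLayout:
    """Magnetometer positions and unit orientations (one per channel)."""

    positions: np.ndarray  # (n_channels, 3) m
    orientations: np.ndarray  # (n_channels, 3) unit vectors
    names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        norms = np.linalg.norm(self.orientations, axis=1, keepdims=True)
        self.orientations = self.orientations / norms

    @property
    def n_channels(self) -> int:
        return len(self.positions)


@dataclass
class SourceGrid:
    """Regular cubic grid of candidate source nodes inside the conductor."""

    positions: np.ndarray  # (n_nodes, 3) m
    ijk: np.ndarray  # (n_nodes, 3) integer grid coordinates
    step: float  # grid step in m

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.ijk = np.asarray(self.ijk, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """Near-uniform unit vectors on the spherical cap z >= z_min."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    k = np.arange(n)
    z = z_min + (1.0 - z_min) * (k + 0.5) / n
    phi = 2.0 * np.pi * k / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def toy_sensor_layout(
    n_channels: int = 24,
    radius: float = 0.102,
    z_min: float = 0.05,
    center: np.ndarray | None = None,
) -> SensorLayout:
    """Magnetometer cap above the head sphere with radial orientations.

    ``z_min`` is the lowest relative height of the cap (fraction of the
    sensor-shell radius), so the layout covers the upper part of the head
    the way a helmet array does.
    """
    if center is None:
        center = np.zeros(3)
    units = _fibonacci_cap(n_channels, z_min)
    positions = center + radius * units
    names = [f"MAG{i:03d}" for i in range(n_channels)]
    return SensorLayout(positions=positions, orientations=units, names=names)


def toy_source_grid(
    step: float = 0.005,
    shape: tuple[int, int, int] = (5, 5, 5),
    center: np.ndarray | None = None,
) -> SourceGrid:
    """Cubic block of source nodes, default 5x5x5 at 5 mm step.

    Centred in the upper half of the head sphere so every node is well
    inside the conductor and none is radial-degenerate at the origin.
    """
    if center is None:
        center = np.array([0.0, 0.0, 0.045])
    ni, nj, nk = shape
    ii, jj, kk = np.meshgrid(
        np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    offsets = (ijk - (np.array(shape) - 1) / 2.0) * step
    return SourceGrid(positions=center + offsets, ijk=ijk, step=step)


def head_source_grid(
    step: float = 0.015,
    shape: tuple[int, int, int] = (9, 9, 4),
    center: np.ndarray | None = None,
    sphere: Sphere | None = None,
    margin: float = 0.005,
) -> SourceGrid:
    """Coarse grid spanning the upper head volume for the source pipeline.

    Covers the lateral temporal and frontal regions where the simulated
    generators sit; nodes falling outside the conductor (minus ``margin``)
    are dropped, so edge nodes naturally have fewer than 26 neighbours.
    """
    if center is None:
        center = np.array([0.0, 0.0, 0.035])
    if sphere is None:
        sphere = Sphere()
    grid = toy_source_grid(step=step, shape=shape, center=center)
    r = np.linalg.norm(grid.positions - sphere.center, axis=1)
    keep = r < sphere.radius - margin
    return SourceGrid(
        positions=grid.positions[keep], ijk=grid.ijk[keep], step=step
    )
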