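"""Analytic single-sphere MEG forward model (Sarvas solution).

For a current dipole inside a homogeneous spherical conductor the magnetic
field outside the sphere has a closed form that is independent of the
conductivity profile. Two classical properties are exploited as checks:

* a radially oriented dipole produces no external magnetic field;
* the radial component of the external field equals the Biot–Savart field
  of the primary dipole alone (volume currents contribute no radial field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SensorLayout, SourceGrid, Sphere

__all__ = ["ForwardModel", "dipole_field", "primary_radial_field", "build_forward"]

MU0_OVER_4PI = 1e-7  # mu_0 / (4 pi), SI


@dataclass
class ForwardModel:
    """Leadfield mapping unit dipole moments at grid nodes to magnetometers.

    ``leadfield`` has shape (n_nodes, 3, n_channels): field along each
    sensor's orientation for a unit moment (1 A·m) along x, y, z.
    """

    leadfield: np.ndarray
    grid: SourceGrid
    sensors: SensorLayout
    sphere: Sphere

    @property
    def n_nodes(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[2]


def dipole_field(
    r0: np.ndarray, q: np.ndarray, sensors_pos: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Magnetic field B (T) of a dipole q (A·m) at r0 inside a sphere.

    Sarvas closed form, vectorised over sensor positions. Positions are
    expressed relative to the sphere centre internally.
    """
    r0 = np.asarray(r0, dtype=float) - center
    r = np.atleast_2d(sensors_pos).astype(float) - center
    q = np.asarray(q, dtype=float)

    a_vec = r - r0  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("sensor coincides with the dipole position")
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - np.einsum("j,ij->i", r0, r))
    # gradient of F with respect to the sensor position
    coef_r = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
    coef_r0 = a + 2.0 * rn + ar / a
    gradF = coef_r[:, None] * r - coef_r0[:, None] * r0[None, :]

    qxr0 = np.cross(q, r0)  # (3,)
    qxr0_dot_r = r @ qxr0
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - qxr0_dot_r[:, None] * gradF
    )
    return B


def primary_radial_field(
    r0: np.ndarray, q: np.ndarray, sensors_pos: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Radial component of the primary (Biot–Savart) dipole field.

    Outside a spherically symmetric conductor this equals the radial
    component of the total field; used as an independent oracle.
    """
    r0 = np.asarray(r0, dtype=float) - center
    r = np.atleast_2d(sensors_pos).astype(float) - center
    d = r - r0
    dn = np.linalg.norm(d, axis=1)
    Bp = MU0_OVER_4PI * np.cross(q, d) / dn[:, None] ** 3
    rhat = r / np.linalg.norm(r, axis=1, keepdims=True)
    return np.einsum("ij,ij->i", Bp, rhat)


def build_forward(
    grid: SourceGrid, sensors: SensorLayout, sphere: Sphere | None = None
) -> ForwardModel:
    """Leadfield for every grid node and cardinal moment orientation.

    Raises if any sensor lies inside the conductor, any node outside it,
    or a node sits at the sphere centre (where the model is degenerate).
    """
    if sphere is None:
        sphere = Sphere()
    center = np.asarray(sphere.center, dtype=float)

    sens_r = np.linalg.norm(sensors.positions - center, axis=1)
    if np.any(sens_r <= sphere.radius):
        raise ValueError("all sensors must lie outside the conductor sphere")
    node_r = np.linalg.norm(grid.positions - center, axis=1)
    if np.any(node_r >= sphere.radius):
        raise ValueError("all grid nodes must lie inside the conductor sphere")
    if np.any(node_r < 1e-9):
        raise ValueError("node at sphere centre is degenerate (no external field)")
    d2 = np.linalg.norm(
        grid.positions[:, None, :] - sensors.positions[None, :, :], axis=-1
    )
    if np.any(d2 < 1e-9):
        raise ValueError("grid node coincides with a sensor")

    L = np.empty((grid.n_nodes, 3, sensors.n_channels))
    eye = np.eye(3)
    for n, r0 in enumerate(grid.positions):
        for k in range(3):
            B = dipole_field(r0, eye[k], sensors.positions, center)
            L[n, k] = np.einsum("ij,ij->i", B, sensors.orientations)
    return ForwardModel(leadfield=L, grid=grid, sensors=sensors, sphere=sphere)
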