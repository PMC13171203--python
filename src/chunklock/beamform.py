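"""LCMV Hilbert beamformer on the toy spherical geometry.

A linearly constrained minimum-variance spatial filter is computed from the
regularized sensor covariance (C' = C + lambda * trace(C)/n * I, lambda
default 5%) with a fixed per-node orientation along the axis of most
reconstructed source variance (principal axis of (L^T C'^-1 L)^-1) and
unit-noise-gain weight normalization (||w|| = 1) against depth bias. The
filter is applied to the Hilbert-transformed (analytic) single-trial data,
yielding complex source time courses from which node-wise phase, magnitude
and inter-trial phase coherence follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .cluster import ClusterTestResult, build_grid_adjacency, permutation_test
from .containers import EpochSet
from .forward import ForwardModel
from .phase import itpc

__all__ = [
    "SpatialFilter",
    "covariance",
    "lcmv_filter",
    "hilbert_beamform",
    "source_itpc_by_level",
    "source_itpc_regression",
]


@dataclass
class SpatialFilter:
    """Per-node LCMV weights (unit norm) and fixed orientations."""

    weights: np.ndarray  # (n_nodes, n_channels)
    orientations: np.ndarray  # (n_nodes, 3) unit vectors
    lam: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.weights, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("weights must be unit-noise-gain normalized")


def covariance(epochs: EpochSet, window: tuple[float, float]) -> np.ndarray:
    """Pooled channel covariance over all trials within a time window.

    Each trial is demeaned per channel inside the window; outer products
    are pooled over trials and samples. Warns when the result is nearly
    rank deficient.
    """
    tmin, tmax = window
    if tmin < epochs.times[0] - 1e-9 or tmax > epochs.times[-1] + 1e-9:
        raise ValueError("covariance window outside epoch support")
    keep = (epochs.times >= tmin - 1e-12) & (epochs.times <= tmax + 1e-12)
    X = epochs.data[:, :, keep]
    X = X - X.mean(axis=2, keepdims=True)
    n_samples = X.shape[0] * X.shape[2]
    C = np.einsum("tcs,tds->cd", X, X) / n_samples
    eig = np.linalg.eigvalsh(C)
    if eig[0] < 1e-10 * eig[-1]:
        warnings.warn(
            f"covariance nearly rank deficient (min/max eig = {eig[0] / eig[-1]:.2e})",
            stacklevel=2,
        )
    return C


def lcmv_filter(
    cov: np.ndarray, forward: ForwardModel, lam: float = 0.05
) -> SpatialFilter:
    """Unit-noise-gain LCMV filter with fixed per-node orientation.

    The orientation is the principal axis of the reconstructed source
    covariance (L^T C'^-1 L)^-1, i.e. the axis of most variance. For the
    sphere model the radial leadfield column vanishes, so the 3x3 system
    is solved in the leadfield's non-degenerate subspace.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-12 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    n = cov.shape[0]
    creg = cov + lam * (np.trace(cov) / n) * np.eye(n)
    cond = np.linalg.cond(creg)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"regularized covariance numerically singular (cond={cond:.2e})"
        )
    cinv = np.linalg.inv(creg)

    L = forward.leadfield  # (nodes, 3, channels)
    n_nodes = L.shape[0]
    weights = np.empty((n_nodes, n))
    orientations = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        Lk = L[k].T  # channels x 3
        # restrict to the non-degenerate moment subspace (rank 2 on a sphere)
        U, s, Vt = np.linalg.svd(Lk, full_matrices=False)
        rank = int(np.sum(s > 1e-8 * s[0]))
        Lr = Lk @ Vt[:rank].T  # channels x rank
        G = Lr.T @ cinv @ Lr
        S = np.linalg.inv(G)  # reconstructed source covariance (rank x rank)
        evals, evecs = np.linalg.eigh(S)
        u_r = evecs[:, -1]  # principal axis in the reduced basis
        ori = Vt[:rank].T @ u_r
        ori = ori / np.linalg.norm(ori)
        lo = Lk @ ori
        w = cinv @ lo / (lo @ cinv @ lo)
        w = w / np.linalg.norm(w)
        weights[k] = w
        orientations[k] = ori
    return SpatialFilter(weights=weights, orientations=orientations, lam=lam)


def hilbert_beamform(epochs: EpochSet, filt: SpatialFilter) -> np.ndarray:
    """Complex analytic source signals, (nodes, trials, time).

    The single-trial data are Hilbert-transformed and the spatial filter is
    applied to the analytic signal; because both operations are linear the
    order is immaterial (asserted in tests).
    """
    analytic = hilbert(epochs.data, axis=-1)  # trials x channels x time
    return np.einsum("nc,tcs->nts", filt.weights, analytic)


def source_itpc_by_level(
    source_signals: np.ndarray,
    levels: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    n_levels: int,
) -> np.ndarray:
    """Node-wise ITPC per level, averaged over a fixed time window.

    ``source_signals`` is the complex (nodes, trials, time) output of
    :func:`hilbert_beamform` for one participant; trials are pooled over
    recording blocks. Returns (levels, nodes).
    """
    keep = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    phases = np.angle(source_signals[:, :, keep])  # nodes x trials x win
    out = np.zeros((n_levels, source_signals.shape[0]))
    for li in range(n_levels):
        mask = levels == li + 1
        if mask.sum() >= 2:
            out[li] = itpc(phases[:, mask, :], axis=1).mean(axis=-1)
    return out


def source_itpc_regression(
    itpc_by_participant: np.ndarray,
    forward: ForwardModel,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    node_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """One-sided cluster regression of source ITPC across levels.

    ``itpc_by_participant`` is (participants, levels, nodes), already
    averaged over the analysis window. ``node_mask`` restricts testing to
    a labeled subset of nodes (standing in for atlas-defined cortical
    regions); the grid adjacency (<= 26 neighbours) is recomputed on the
    subset. No minimum-channel pruning is applied in source space.
    """
    data = np.asarray(itpc_by_participant, dtype=float)
    grid = forward.grid
    if node_mask is not None:
        node_mask = np.asarray(node_mask, dtype=bool)
        data = data[:, :, node_mask]
        from .geometry import SourceGrid

        grid = SourceGrid(
            positions=grid.positions[node_mask],
            ijk=grid.ijk[node_mask],
            step=grid.step,
        )
    adjacency = build_grid_adjacency(grid)
    return permutation_test(
        data[:, :, :, None],
        adjacency,
        n_perm=n_perm,
        sided="pos",
        alpha=alpha,
        min_channels=1,
        rng=rng,
    )
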