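"""Mass-univariate level regression with cluster-based permutation inference.

Per (channel, time) cell, each participant's ordinary-least-squares slope of
the cell value on the ordered duration level (1..7) is computed; a one-sample
t statistic over participants' slopes (df = n_participants - 1) forms the
cell-level map. Supra-threshold cells of equal sign are merged into clusters
through the spatial adjacency (at equal time) united with temporal
succession (at equal channel); clusters spanning fewer than ``min_channels``
distinct channels are pruned. Each observed cluster's summed t is compared
against the permutation null of the maximum cluster sum, where the
exchangeability unit is the set of level labels within each participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .geometry import SensorLayout, SourceGrid

__all__ = [
    "Adjacency",
    "Cluster",
    "ClusterTestResult",
    "build_sensor_adjacency",
    "build_grid_adjacency",
    "level_regression_stat",
    "form_clusters",
    "permutation_test",
]

T_CAP = 1e6  # stand-in for an infinite t when slopes have exactly zero variance


@dataclass
class Adjacency:
    """Symmetric, irreflexive neighbour relation over spatial cells."""

    n: int
    pairs: np.ndarray  # (m, 2) with i < j, unique

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        if len(pairs) and np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("adjacency must be irreflexive")
        self.pairs = np.unique(pairs, axis=0) if len(pairs) else pairs

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n, dtype=int)
        if len(self.pairs):
            np.add.at(counts, self.pairs[:, 0], 1)
            np.add.at(counts, self.pairs[:, 1], 1)
        return counts


def build_sensor_adjacency(
    layout: SensorLayout, distance: float | None = None
) -> Adjacency:
    """Sensors within ``distance`` metres are neighbours.

    Default distance: 1.5x the median nearest-neighbour spacing, which
    connects each sensor to its surrounding ring on a regular cap.
    Isolated sensors are allowed (logged via warning).
    """
    pos = layout.positions
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if distance is None:
        distance = 1.5 * float(np.median(d.min(axis=1)))
    ii, jj = np.nonzero(np.triu(d <= distance, k=1))
    adj = Adjacency(n=len(pos), pairs=np.column_stack([ii, jj]))
    lonely = np.flatnonzero(adj.neighbor_counts() == 0)
    if len(lonely):
        warnings.warn(f"isolated sensor(s): {lonely.tolist()}", stacklevel=2)
    return adj


def build_grid_adjacency(grid: SourceGrid) -> Adjacency:
    """Grid nodes within one step in every dimension (<= 26 neighbours)."""
    ijk = grid.ijk
    diff = np.abs(ijk[:, None, :] - ijk[None, :, :])
    near = (diff <= 1).all(axis=-1) & (diff.sum(axis=-1) > 0)
    ii, jj = np.nonzero(np.triu(near, k=1))
    return Adjacency(n=len(ijk), pairs=np.column_stack([ii, jj]))


def level_regression_stat(data: np.ndarray) -> np.ndarray:
    """One-sample t over per-participant OLS slopes of cell value on level.

    ``data`` is (participants, levels, *cells); returns a t map over cells
    with df = participants - 1. Cells where all participants have exactly
    the same slope get a capped t (sign preserved; 0 if the slope is 0).
    """
    data = np.asarray(data, dtype=float)
    P, L = data.shape[:2]
    if P < 2 or L < 2:
        raise ValueError("need >= 2 participants and >= 2 levels")
    levels = np.arange(1, L + 1, dtype=float)
    c = levels - levels.mean()
    w = c / np.sum(c**2)
    slopes = np.einsum("l,pl...->p...", w, data)
    scale = np.sqrt(np.mean(data**2, axis=(0, 1))) + np.finfo(float).tiny
    return _slopes_to_t(slopes, scale, axis=0)


def _slopes_to_t(slopes: np.ndarray, scale: np.ndarray, axis: int) -> np.ndarray:
    """One-sample t over ``axis`` with an exact-zero-variance branch.

    ``scale`` is the per-cell data magnitude; slope means and SDs below
    1e-12 of it are round-off from exactly constant inputs and map to
    t = 0 (or a capped t when the common slope is genuinely nonzero).
    """
    P = slopes.shape[axis]
    mean = slopes.mean(axis=axis)
    sd = slopes.std(axis=axis, ddof=1)
    tol = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean * np.sqrt(P) / sd
    zero_var = sd <= tol
    capped = np.where(np.abs(mean) <= tol, 0.0, np.sign(mean) * T_CAP)
    return np.where(zero_var, capped, t)


@dataclass
class Cluster:
    """Spatiotemporally contiguous set of supra-threshold cells."""

    cells: np.ndarray  # (k, 2) array of (channel, time) indices
    sign: int
    cluster_sum: float
    p_value: float | None = None

    @property
    def channels(self) -> np.ndarray:
        return np.unique(self.cells[:, 0])

    @property
    def time_indices(self) -> np.ndarray:
        return np.unique(self.cells[:, 1])


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray  # (channels, time)
    threshold: float
    null_max_pos: np.ndarray = field(default_factory=lambda: np.array([]))
    null_max_neg: np.ndarray = field(default_factory=lambda: np.array([]))
    sided: str = "two"
    alpha: float = 0.05

    @property
    def per_sign_alpha(self) -> float:
        return self.alpha / 2 if self.sided == "two" else self.alpha

    def significant(self) -> list[Cluster]:
        a = self.per_sign_alpha
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= a]


def _cell_graph(adjacency: Adjacency, n_time: int) -> sparse.csr_matrix:
    """Connectivity over flattened (channel, time) cells."""
    S = adjacency.n
    rows, cols = [], []
    if len(adjacency.pairs):
        t = np.arange(n_time)
        i = (adjacency.pairs[:, 0][:, None] * n_time + t[None, :]).ravel()
        j = (adjacency.pairs[:, 1][:, None] * n_time + t[None, :]).ravel()
        rows.append(i)
        cols.append(j)
    if n_time > 1:
        s = np.arange(S)
        t = np.arange(n_time - 1)
        i = (s[:, None] * n_time + t[None, :]).ravel()
        rows.append(i)
        cols.append(i + 1)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.array([], dtype=int)
    n = S * n_time
    g = sparse.coo_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
    return (g + g.T).tocsr()


def _components(
    graph: sparse.csr_matrix, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return idx, np.array([], dtype=int), 0
    sub = graph[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return idx, labels, n_comp


def _clusters_one_sign(
    flat_stat: np.ndarray,
    graph: sparse.csr_matrix,
    n_time: int,
    threshold: float,
    sign: int,
    min_channels: int,
) -> list[Cluster]:
    mask = sign * flat_stat > threshold
    idx, labels, n_comp = _components(graph, mask)
    out = []
    for k in range(n_comp):
        members = idx[labels == k]
        ch = members // n_time
        if len(np.unique(ch)) < min_channels:
            continue
        cells = np.column_stack([ch, members % n_time])
        out.append(
            Cluster(cells=cells, sign=sign, cluster_sum=float(flat_stat[members].sum()))
        )
    return out


def _max_cluster_sum(
    flat_stat: np.ndarray,
    graph: sparse.csr_matrix,
    n_time: int,
    threshold: float,
    sign: int,
    min_channels: int,
) -> float:
    mask = sign * flat_stat > threshold
    idx, labels, n_comp = _components(graph, mask)
    if n_comp == 0:
        return 0.0
    sums = np.bincount(labels, weights=flat_stat[idx], minlength=n_comp)
    ch = idx // n_time
    n_channels_total = flat_stat.size // n_time
    # distinct channels per component via unique (label, channel) pairs
    uniq_pairs = np.unique(labels.astype(np.int64) * n_channels_total + ch)
    n_ch = np.bincount(uniq_pairs // n_channels_total, minlength=n_comp)
    ok = n_ch >= min_channels
    if not ok.any():
        return 0.0
    return float(np.max(sign * sums[ok]))


def form_clusters(
    stat_map: np.ndarray,
    threshold: float,
    adjacency: Adjacency,
    min_channels: int = 3,
    tail: str = "both",
) -> list[Cluster]:
    """Connected components of same-sign supra-threshold cells.

    ``stat_map`` is (channels, time); connectivity is spatial adjacency at
    equal time plus temporal succession at equal channel. Clusters covering
    fewer than ``min_channels`` distinct channels anywhere are pruned.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    stat_map = np.atleast_2d(np.asarray(stat_map, dtype=float))
    S, T = stat_map.shape
    if adjacency.n != S:
        raise ValueError("adjacency size does not match number of channels")
    graph = _cell_graph(adjacency, T)
    flat = stat_map.ravel()
    signs = {"both": (1, -1), "pos": (1,), "neg": (-1,)}[tail]
    clusters: list[Cluster] = []
    for sign in signs:
        clusters.extend(
            _clusters_one_sign(flat, graph, T, threshold, sign, min_channels)
        )
    return clusters


def _perm_t_maps(
    data2d: np.ndarray, w: np.ndarray, perms: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """t maps for a block of level-label permutations.

    ``data2d`` is (P, L, N); ``perms`` is (R, P, L) of permuted level
    indices. Returns (R, N).
    """
    W = w[perms]  # (R, P, L)
    slopes = np.einsum("rpl,pln->rpn", W, data2d)
    return _slopes_to_t(slopes, scale[None, :], axis=1)


def permutation_test(
    data: np.ndarray,
    adjacency: Adjacency,
    n_perm: int = 10_000,
    sided: str = "two",
    alpha: float = 0.05,
    threshold: float | None = None,
    min_channels: int = 3,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """Cluster-based permutation regression across ordered levels.

    ``data`` is (participants, levels, channels, time). Level labels are
    permuted independently within each participant (exchangeable under the
    null of no level effect). The null distribution is the maximum cluster
    sum per permutation and sign; observed p-values use the "+1" convention
    (the observed statistic is a member of its own null), so
    p >= 1/(n_perm + 1). Two-sided significance is assessed at alpha/2 per
    sign; one-sided ('pos' tail) at alpha.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    P, L, S, T = data.shape
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse",
                      stacklevel=2)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if threshold is None:
        # parametric two-tailed t threshold at p = 0.05, the framework default
        threshold = float(t_dist.ppf(1 - 0.025, df=P - 1))

    levels = np.arange(1, L + 1, dtype=float)
    c = levels - levels.mean()
    w = c / np.sum(c**2)

    data2d = data.reshape(P, L, S * T)
    cell_scale = np.sqrt(np.mean(data2d**2, axis=(0, 1))) + np.finfo(float).tiny
    t_obs = level_regression_stat(data2d).reshape(S, T)
    graph = _cell_graph(adjacency, T)
    flat_obs = t_obs.ravel()

    tails = (1, -1) if sided == "two" else ((1,) if sided in ("one", "pos") else (-1,))
    clusters: list[Cluster] = []
    for sign in tails:
        clusters.extend(
            _clusters_one_sign(flat_obs, graph, T, threshold, sign, min_channels)
        )

    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    need_pos = 1 in tails
    need_neg = -1 in tails
    # chunk permutations so the (R, P, N) slope array stays modest
    chunk = max(1, min(n_perm, int(1e7 // max(P * S * T, 1)) or 1))
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((r, P, L)), axis=-1)
        t_perm = _perm_t_maps(data2d, w, perms, cell_scale)  # (r, N)
        for i in range(r):
            flat = t_perm[i]
            if need_pos:
                null_pos[done + i] = _max_cluster_sum(
                    flat, graph, T, threshold, 1, min_channels
                )
            if need_neg:
                null_neg[done + i] = -_max_cluster_sum(
                    flat, graph, T, threshold, -1, min_channels
                )
        done += r

    for cl in clusters:
        null = null_pos if cl.sign > 0 else null_neg
        exceed = np.sum(cl.sign * null >= cl.sign * cl.cluster_sum)
        cl.p_value = float((1 + exceed) / (1 + n_perm))

    return ClusterTestResult(
        clusters=sorted(clusters, key=lambda c: -abs(c.cluster_sum)),
        t_map=t_obs,
        threshold=threshold,
        null_max_pos=null_pos if need_pos else np.array([]),
        null_max_neg=null_neg if need_neg else np.array([]),
        sided=sided,
        alpha=alpha,
    )
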