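"""End-to-end analysis pipeline over the synthetic dataset.

Stages mirror the analysis order of the study the package emulates:
simulate → preprocess (filter, epoch, reject, decimate) → sensor-level
ITPC and ERF cluster regressions → ERF~ITPC link models → source-level
beamformer regression → behavioral models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as beh
from . import beamform as bf
from .cluster import (
    ClusterTestResult,
    build_sensor_adjacency,
    permutation_test,
)
from .config import AnalysisConfig, SimConfig
from .containers import EpochSet
from .erf_link import link_cluster
from .forward import ForwardModel, build_forward
from .geometry import Sphere, head_source_grid, toy_sensor_layout
from .phase import ERFMap, ITPCMap, analytic_phase, itpc
from .preprocess import FilterSpec, butter_filter, downsample, epoch, reject_artifacts
from .synthgen import generate_behavior, generate_nback, generate_session

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantResult",
    "preprocess_session",
    "run_participant",
    "run_sensor_stage",
    "sensor_cluster_tests",
    "run_link_stage",
    "run_source_stage",
    "run_behavior_stage",
    "crop_window",
]


def preprocess_session(
    signal: np.ndarray,
    events: np.ndarray,
    metadata: pd.DataFrame,
    sim: SimConfig,
    ana: AnalysisConfig,
) -> tuple[EpochSet, EpochSet, pd.DataFrame]:
    """Broadband and narrow-band cleaned epochs at the target rate.

    Continuous data are band-limited (0.2 Hz high-pass, 30 Hz low-pass,
    two-pass Butterworth), segmented around the boundary events, artifact
    rejected on the broadband signal, decimated, and finally a 4 Hz
    low-pass isolates the delta band for phase analysis. Returns
    (broadband, narrowband, rejection_log).
    """
    sfreq = sim.sfreq_raw
    x = butter_filter(
        signal, FilterSpec("highpass", ana.highpass, ana.highpass_order), sfreq
    )
    if ana.lowpass_broad < sfreq / 2:
        x = butter_filter(
            x, FilterSpec("lowpass", ana.lowpass_broad, ana.lowpass_broad_order), sfreq
        )
    epochs = epoch(x, events, sim.epoch_window, sfreq, metadata=metadata)
    clean, log = reject_artifacts(
        epochs, z_thresh=ana.z_thresh, amp_thresh=ana.amp_thresh,
        median_order=ana.median_order,
    )
    broad = downsample(clean, ana.sfreq_target)
    narrow = broad.copy()
    narrow.data = butter_filter(
        narrow.data,
        FilterSpec("lowpass", ana.lowpass_narrow, ana.lowpass_narrow_order),
        broad.sfreq,
    )
    return broad, narrow, log


@dataclass
class ParticipantResult:
    """Per-participant level-resolved maps and source ITPC."""

    participant: int
    itpc: np.ndarray  # (levels, channels, time) from the narrow band
    erf_broad: np.ndarray  # (levels, channels, time)
    erf_delta: np.ndarray  # (levels, channels, time)
    n_trials: np.ndarray  # (levels,)
    times: np.ndarray
    trials: pd.DataFrame  # full session trial table with a 'kept' flag
    rejected: pd.DataFrame
    source_itpc: np.ndarray | None = None  # (levels, nodes)


def _per_level_maps(
    narrow: EpochSet, broad: EpochSet, n_levels: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    phases = analytic_phase(narrow.data)
    lv = narrow.metadata["level"].to_numpy()
    n_ch, n_t = narrow.n_channels, narrow.n_times
    itpc_vals = np.zeros((n_levels, n_ch, n_t))
    erf_broad = np.zeros((n_levels, n_ch, n_t))
    erf_delta = np.zeros((n_levels, n_ch, n_t))
    counts = np.zeros(n_levels, dtype=int)
    for li in range(n_levels):
        mask = lv == li + 1
        counts[li] = mask.sum()
        if counts[li] >= 2:
            itpc_vals[li] = itpc(phases[mask], axis=0)
        if counts[li] >= 1:
            erf_broad[li] = broad.data[mask].mean(axis=0)
            erf_delta[li] = narrow.data[mask].mean(axis=0)
    return itpc_vals, erf_broad, erf_delta, counts


def run_participant(
    sim: SimConfig,
    ana: AnalysisConfig,
    participant: int,
    forward: ForwardModel | None = None,
) -> ParticipantResult:
    """Simulate, preprocess and analyse one participant.

    If ``forward`` is given, the LCMV Hilbert beamformer is applied with a
    participant-specific common filter and node-wise ITPC is averaged over
    the source analysis window.
    """
    signal, events, metadata, _ = generate_session(sim, participant)
    broad, narrow, log = preprocess_session(signal, events, metadata, sim, ana)
    itpc_vals, erf_broad, erf_delta, counts = _per_level_maps(
        narrow, broad, sim.n_levels
    )
    trials = metadata[["participant", "trial", "level", "block"]].copy()
    trials["kept"] = trials["trial"].isin(narrow.metadata["trial"]).to_numpy()
    result = ParticipantResult(
        participant=participant,
        itpc=itpc_vals,
        erf_broad=erf_broad,
        erf_delta=erf_delta,
        n_trials=counts,
        times=narrow.times,
        trials=trials,
        rejected=log,
    )
    if forward is not None:
        cov_win = (
            max(ana.cov_window[0], narrow.times[0]),
            min(ana.cov_window[1], narrow.times[-1]),
        )
        cov = bf.covariance(narrow, cov_win)
        filt = bf.lcmv_filter(cov, forward, lam=ana.lcmv_lambda)
        # Hilbert over the full epoch, then weight only the analysis window:
        # the spatial filter is time-invariant, so this equals beamforming
        # the whole epoch and cropping, at a fraction of the memory
        from scipy.signal import hilbert as _hilbert

        analytic = _hilbert(narrow.data, axis=-1)
        keep = (narrow.times >= ana.source_window[0] - 1e-12) & (
            narrow.times <= ana.source_window[1] + 1e-12
        )
        src = np.einsum("nc,tcs->nts", filt.weights, analytic[:, :, keep])
        result.source_itpc = bf.source_itpc_by_level(
            src,
            narrow.metadata["level"].to_numpy(),
            narrow.times[keep],
            ana.source_window,
            sim.n_levels,
        )
    return result


def run_sensor_stage(
    sim: SimConfig,
    ana: AnalysisConfig,
    with_source: bool = False,
) -> dict:
    """All participants' maps stacked into group arrays."""
    forward = None
    if with_source:
        grid = head_source_grid()
        sensors = toy_sensor_layout(sim.n_channels)
        forward = build_forward(grid, sensors, Sphere())
    results = [
        run_participant(sim, ana, p, forward=forward)
        for p in range(sim.n_participants)
    ]
    parts = np.array([r.participant for r in results])
    times = results[0].times
    levels = np.arange(1, sim.n_levels + 1)
    counts = np.stack([r.n_trials for r in results])
    itpc_map = ITPCMap(
        values=np.stack([r.itpc for r in results]),
        n_trials=counts,
        times=times,
        participants=parts,
        levels=levels,
    )
    erf_map = ERFMap(
        values=np.stack([r.erf_broad for r in results]),
        n_trials=counts.copy(),
        times=times,
        participants=parts,
        levels=levels,
    )
    delta_erf_map = ERFMap(
        values=np.stack([r.erf_delta for r in results]),
        n_trials=counts.copy(),
        times=times,
        participants=parts,
        levels=levels,
    )
    out = {
        "itpc_map": itpc_map,
        "erf_map": erf_map,
        "delta_erf_map": delta_erf_map,
        "trials": pd.concat([r.trials for r in results], ignore_index=True),
        "rejections": pd.concat(
            [r.rejected.assign(participant=r.participant) for r in results],
            ignore_index=True,
        ),
        "forward": forward,
    }
    if with_source:
        out["source_itpc"] = np.stack([r.source_itpc for r in results])
    return out


def crop_window(values: np.ndarray, times: np.ndarray, window: tuple[float, float]):
    """Crop the trailing time axis of (P, L, C, T) values to a window."""
    keep = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    return values[..., keep], times[keep]


def sensor_cluster_tests(
    itpc_map: ITPCMap,
    erf_map: ERFMap,
    sim: SimConfig,
    ana: AnalysisConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, ClusterTestResult]:
    """Two-sided cluster regressions of ITPC and ERF across levels."""
    layout = toy_sensor_layout(sim.n_channels)
    adjacency = build_sensor_adjacency(layout)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = {}
    for name, vmap in (("itpc", itpc_map), ("erf", erf_map)):
        vals, _ = crop_window(vmap.values, vmap.times, ana.stat_window)
        out[name] = permutation_test(
            vals,
            adjacency,
            n_perm=ana.n_perm,
            sided="two",
            alpha=ana.alpha,
            min_channels=ana.min_channels,
            rng=rng,
        )
    return out


def run_link_stage(
    itpc_map: ITPCMap,
    erf_map: ERFMap,
    delta_erf_map: ERFMap,
    itpc_test: ClusterTestResult,
    ana: AnalysisConfig,
    max_cells: int | None = None,
) -> dict:
    """ERF~ITPC mixed models within the observed ITPC clusters.

    Both the broadband and the delta-band (4 Hz re-filtered) amplitude
    variants are fitted; maps are first cropped to the statistics window
    so cluster cell indices align. ``max_cells`` caps the per-cluster cell
    count by deterministic striding (large clusters on dense grids would
    otherwise require thousands of mixed-model fits).
    """
    from dataclasses import replace as _dc_replace

    win_itpc = _cropped_map(itpc_map, ana.stat_window)
    win_erf = _cropped_map(erf_map, ana.stat_window)
    win_delta = _cropped_map(delta_erf_map, ana.stat_window)
    clusters = itpc_test.significant() or itpc_test.clusters
    tables = {}
    for idx, cl in enumerate(clusters):
        fit_cl = cl
        if max_cells is not None and len(cl.cells) > max_cells:
            stride = int(np.ceil(len(cl.cells) / max_cells))
            fit_cl = _dc_replace(cl, cells=cl.cells[::stride])
        tables[f"cluster{idx}_broadband"] = link_cluster(win_erf, win_itpc, fit_cl)
        tables[f"cluster{idx}_delta"] = link_cluster(win_delta, win_itpc, fit_cl)
    return {"tables": tables, "clusters": clusters}


def _cropped_map(vmap, window):
    vals, times = crop_window(vmap.values, vmap.times, window)
    cls = type(vmap)
    return cls(
        values=vals,
        n_trials=vmap.n_trials,
        times=times,
        participants=vmap.participants,
        levels=vmap.levels,
    )


def run_source_stage(
    source_itpc: np.ndarray,
    forward: ForwardModel,
    ana: AnalysisConfig,
    node_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """One-sided cluster regression of window-averaged node ITPC."""
    return bf.source_itpc_regression(
        source_itpc,
        forward,
        n_perm=ana.n_perm,
        alpha=ana.alpha,
        node_mask=node_mask,
        rng=rng,
    )


def extract_feature_cells(link_tables: dict[str, pd.DataFrame]) -> dict:
    """Strongest positive and negative amplitude~ITPC cells (broadband)."""
    broad = [t for k, t in link_tables.items() if k.endswith("broadband")]
    if not broad:
        raise ValueError("no broadband link tables")
    allcells = pd.concat(broad, ignore_index=True)
    pos = allcells.loc[allcells["t_value"].idxmax()]
    neg = allcells.loc[allcells["t_value"].idxmin()]
    return {
        "positive": (int(pos["channel"]), int(pos["time_index"]), float(pos["t_value"])),
        "negative": (int(neg["channel"]), int(neg["time_index"]), float(neg["t_value"])),
    }


def run_behavior_stage(
    sim: SimConfig,
    ana: AnalysisConfig,
    itpc_map: ITPCMap,
    feature_cell: tuple[int, int],
    trials: pd.DataFrame | None = None,
) -> dict:
    """n-back scoring, median split, behavior generation and both models.

    Responses to trials excluded from the MEG analysis (``kept == False``
    in ``trials``) are removed before the proportion-level model.
    """
    nback = generate_nback(sim)
    scores = beh.score_participants(nback)
    groups = beh.median_split(scores.to_numpy())

    win_map = _cropped_map(itpc_map, ana.stat_window)
    ch, ti = feature_cell
    feature = win_map.values[:, :, ch, ti]  # (P, L)
    feature = np.clip(feature, 0.0, 1.0)

    table = generate_behavior(
        sim, feature, groups,
        trials=trials[["participant", "level", "trial"]] if trials is not None else None,
    )
    level_model = beh.glmm_attachment_level(table)

    excluded = None
    if trials is not None and "kept" in trials:
        excluded = trials.loc[~trials["kept"], ["participant", "trial"]]
    props = beh.attachment_proportions(table, exclude_trials=excluded)
    prop_mat = (
        props.pivot(index="participant", columns="level", values="prop_np2")
        .reindex(np.arange(sim.n_participants))
        .to_numpy()
    )
    prop_mat = np.nan_to_num(prop_mat, nan=0.5)
    interaction = beh.attachment_itpc_interaction(prop_mat, feature, groups)
    return {
        "nback": nback,
        "scores": scores,
        "groups": groups,
        "behavior_table": table,
        "level_model": level_model,
        "interaction": interaction,
        "feature": feature,
        "prop_np2": prop_mat,
    }
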