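"""Analytic phase, inter-trial phase coherence, and evoked fields.

ITPC at a channel and time point is the resultant length of the unit phase
vectors across trials, |n^-1 Σ_j exp(i φ_j)|: 0 for uniform phases, 1 for
perfect alignment. The estimator is the raw resultant length without bias
correction; trial counts are equalised per level by design, so the small
positive bias (E[R^2] = 1/n under uniformity) is comparable across levels
and is logged per cell rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .containers import EpochSet

__all__ = ["analytic_phase", "itpc", "erf", "ITPCMap", "ERFMap", "level_maps"]


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a narrow-band signal via the Hilbert transform.

    Operates along the last axis; returns phase wrapped to (-pi, pi]. The
    input should already be low-passed into the band of interest. A
    constant-zero signal has undefined phase and raises a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.max(np.abs(x)) == 0.0:
        warnings.warn("analytic phase of an all-zero signal is undefined",
                      stacklevel=2)
    return np.angle(hilbert(x, axis=-1))


def itpc(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Resultant length of phases across trials (default axis 0).

    ``phases`` is typically (trials, time) for one channel or
    (trials, channels, time); at least two trials are required.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[axis] < 2:
        raise ValueError("ITPC requires at least 2 trials")
    return np.abs(np.mean(np.exp(1j * phases), axis=axis))


def erf(epochs: EpochSet, level: int | None = None) -> np.ndarray:
    """Trial-averaged evoked field (channels x time), optionally per level."""
    if level is None:
        data = epochs.data
    else:
        mask = epochs.metadata["level"].to_numpy() == level
        data = epochs.data[mask]
    if data.shape[0] < 1:
        raise ValueError(f"no trials at level {level}")
    return data.mean(axis=0)


@dataclass
class ITPCMap:
    """Per-participant, per-level ITPC: (participants, levels, channels, time)."""

    values: np.ndarray
    n_trials: np.ndarray  # (participants, levels)
    times: np.ndarray
    participants: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("ITPC values must lie in [0, 1]")


@dataclass
class ERFMap:
    """Per-participant, per-level evoked field: (participants, levels, channels, time)."""

    values: np.ndarray
    n_trials: np.ndarray
    times: np.ndarray
    participants: np.ndarray
    levels: np.ndarray


def level_maps(
    epochs_by_participant: dict[int, EpochSet],
    n_levels: int,
    phase_extractor=analytic_phase,
) -> tuple[ITPCMap, ERFMap]:
    """Compute ITPC and ERF maps per participant and duration level.

    ``epochs_by_participant`` maps participant id to their (narrow-band)
    cleaned epochs. Both maps share trial-count bookkeeping so the
    rejection mask affects them identically.
    """
    parts = np.array(sorted(epochs_by_participant))
    first = epochs_by_participant[parts[0]]
    n_ch, n_t = first.n_channels, first.n_times
    shape = (len(parts), n_levels, n_ch, n_t)
    itpc_vals = np.zeros(shape)
    erf_vals = np.zeros(shape)
    counts = np.zeros((len(parts), n_levels), dtype=int)
    for pi, p in enumerate(parts):
        ep = epochs_by_participant[p]
        phases = phase_extractor(ep.data)
        lv = ep.metadata["level"].to_numpy()
        for li in range(n_levels):
            mask = lv == li + 1
            counts[pi, li] = mask.sum()
            if mask.sum() >= 2:
                itpc_vals[pi, li] = itpc(phases[mask], axis=0)
            if mask.sum() >= 1:
                erf_vals[pi, li] = ep.data[mask].mean(axis=0)
    itpc_map = ITPCMap(
        values=itpc_vals, n_trials=counts, times=first.times,
        participants=parts, levels=np.arange(1, n_levels + 1),
    )
    erf_map = ERFMap(
        values=erf_vals, n_trials=counts.copy(), times=first.times,
        participants=parts, levels=np.arange(1, n_levels + 1),
    )
    return itpc_map, erf_map
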