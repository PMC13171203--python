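"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Trials x channels x time array with metadata, time-locked to an event.

    ``times`` is in seconds with 0 at the boundary event. ``metadata`` has
    one row per trial and at least the columns ``participant``, ``trial``,
    ``level`` and ``block``; an ``artifact`` boolean column is added by the
    rejection step.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, times)")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            times=self.times.copy(),
            metadata=self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.metadata.iloc[np.atleast_1d(mask)].reset_index(drop=True),
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time axis to [tmin, tmax] (inclusive)."""
        keep = (self.times >= tmin - 1e-12) & (self.times <= tmax + 1e-12)
        return EpochSet(
            data=self.data[:, :, keep],
            sfreq=self.sfreq,
            times=self.times[keep],
            metadata=self.metadata.copy(),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            times=self.times.copy(),
            metadata=self.metadata.copy(),
        )
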