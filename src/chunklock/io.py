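"""On-disk artifact formats.

Epoch containers are NumPy ``.npz`` archives with a plain-text sidecar
documenting axes and alignment; tables are tab-delimited text with a
header; ground truth and model summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_table",
    "load_table",
    "save_json",
    "load_json",
]

_SIDECAR = """\
axes: trial, channel, time
sampling_rate_hz: {sfreq}
t0: boundary event (main clause offset)
time_range_s: {tmin} to {tmax}
n_trials: {n_trials}
n_channels: {n_channels}
metadata: {meta_name}
"""


def save_epochs(epochs: EpochSet, prefix: str | Path) -> None:
    """Write ``<prefix>.npz``, ``<prefix>_metadata.tsv`` and ``<prefix>.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        prefix.with_suffix(".npz"),
        data=epochs.data,
        times=epochs.times,
        sfreq=np.array(epochs.sfreq),
    )
    meta_path = prefix.parent / (prefix.name + "_metadata.tsv")
    epochs.metadata.to_csv(meta_path, sep="\t", index=False)
    prefix.with_suffix(".txt").write_text(
        _SIDECAR.format(
            sfreq=epochs.sfreq,
            tmin=epochs.times[0],
            tmax=epochs.times[-1],
            n_trials=epochs.n_trials,
            n_channels=epochs.n_channels,
            meta_name=meta_path.name,
        )
    )


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as npz:
        data = npz["data"]
        times = npz["times"]
        sfreq = float(npz["sfreq"])
    metadata = pd.read_csv(prefix.parent / (prefix.name + "_metadata.tsv"), sep="\t")
    return EpochSet(data=data, sfreq=sfreq, times=times, metadata=metadata)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
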