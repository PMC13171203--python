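"""Simulation and analysis configuration.

``SimConfig`` pins down the generative study conditions: a 40-participant
auditory experiment with seven sentence-duration levels, 25 trials per
level, raw acquisition at 1000 Hz, an ongoing delta-band oscillator whose
phase is reset at the multi-word chunk boundary with level-dependent von
Mises concentration, 1/f sensor noise, and a behavioral read-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["SimConfig", "AnalysisConfig", "TABLE1_DURATIONS", "load_config"]

# Main-clause duration mean/SD in seconds for the seven levels.
TABLE1_DURATIONS: tuple[tuple[float, float], ...] = (
    (2.09, 0.14),
    (2.35, 0.14),
    (2.66, 0.14),
    (2.94, 0.12),
    (3.23, 0.17),
    (3.47, 0.16),
    (3.78, 0.16),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator.

    ``kappa_by_level`` controls the von Mises concentration of the boundary
    phase reset per level; the default rises monotonically from 0 to 8 so
    phase-locking grows with clause duration. ``target_phase`` is the mean
    reset phase; ``None`` draws one target phase per participant, so the
    reset is consistent within but not across heads (inter-trial phase
    coherence is unaffected, the group-level evoked field is nulled).
    """

    n_participants: int = 40
    n_levels: int = 7
    n_trials_per_level: int = 25
    sfreq_raw: float = 1000.0
    n_channels: int = 24
    delta_freq: float = 1.0 / 2.7  # Hz; one cycle per 2.7 s window
    kappa_by_level: tuple[float, ...] = tuple(float(k) for k in np.linspace(0.0, 8.0, 7))
    target_phase: float | None = None  # radians; None = per-participant draw
    evoked_gain: float = 0.0  # additive evoked component, units of osc_amp
    osc_amp: float = 60e-15  # oscillator amplitude at the sensors, T
    noise_exponent: float = 1.0  # 1/f^alpha power slope
    noise_scale: float = 50e-15  # channel noise SD, T
    level_duration_mean_sd: tuple[tuple[float, float], ...] = TABLE1_DURATIONS
    epoch_window: tuple[float, float] = (-3.0, 3.0)  # s around the boundary
    pad: float = 0.6  # s of tapered padding around each trial block
    behavior_slopes: tuple[float, float] = (0.11, -0.10)  # (low, high) span
    timeout_rate: float = 1.0 / 175.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        errors: list[str] = []
        if self.n_levels < 1:
            errors.append("n_levels must be >= 1")
        if len(self.kappa_by_level) != self.n_levels:
            errors.append(
                f"kappa_by_level has {len(self.kappa_by_level)} entries, "
                f"expected n_levels={self.n_levels}"
            )
        if any(k < 0 for k in self.kappa_by_level):
            errors.append("kappa_by_level entries must be >= 0")
        if len(self.level_duration_mean_sd) != self.n_levels:
            errors.append(
                f"level_duration_mean_sd has {len(self.level_duration_mean_sd)} "
                f"entries, expected n_levels={self.n_levels}"
            )
        if self.sfreq_raw <= 0:
            errors.append("sfreq_raw must be positive")
        if self.delta_freq <= 0 or self.delta_freq >= self.sfreq_raw / 2:
            errors.append("delta_freq must lie in (0, Nyquist)")
        if self.epoch_window[0] >= 0 or self.epoch_window[1] <= 0:
            errors.append("epoch_window must straddle the boundary (t=0)")
        if not 0 <= self.timeout_rate < 1:
            errors.append("timeout_rate must be in [0, 1)")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))
        kappas = np.asarray(self.kappa_by_level)
        if np.any(np.diff(kappas) < 0):
            warnings.warn(
                "kappa_by_level is not monotone non-decreasing; "
                "this is only meaningful for null simulations",
                stacklevel=2,
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisConfig:
    """Parameters of the statistical analysis stages."""

    lowpass_narrow: float = 4.0  # Hz, delta-band isolation
    lowpass_narrow_order: int = 8
    highpass: float = 0.2  # Hz, broadband cleanup
    highpass_order: int = 5
    lowpass_broad: float = 30.0
    lowpass_broad_order: int = 14
    sfreq_target: float = 100.0
    z_thresh: float = 60.0
    amp_thresh: float = 5e-12  # T (+-5 pT)
    median_order: int = 9
    stat_window: tuple[float, float] = (0.0, 1.0)  # s, cluster regression
    source_window: tuple[float, float] = (0.15, 0.38)  # s, source ITPC average
    cov_window: tuple[float, float] = (-0.85, 1.38)  # s, beamformer covariance
    n_perm: int = 10_000
    alpha: float = 0.05
    min_channels: int = 3
    lcmv_lambda: float = 0.05

    def validate(self) -> "AnalysisConfig":
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return self


_SIM_KEYS = {f.name for f in SimConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_ANA_KEYS = {f.name for f in AnalysisConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def _coerce_tuples(d: dict) -> dict:
    out = dict(d)
    for key in ("kappa_by_level", "behavior_slopes", "epoch_window"):
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    if "level_duration_mean_sd" in out:
        out["level_duration_mean_sd"] = tuple(
            tuple(pair) for pair in out["level_duration_mean_sd"]
        )
    for key in ("stat_window", "source_window", "cov_window"):
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    return out


def load_config(path: str) -> tuple[SimConfig, AnalysisConfig, list[str]]:
    """Read a YAML config; returns (sim, analysis, errors).

    Unknown keys are reported rather than silently dropped; an empty file
    yields full defaults. On any error the defaults are returned alongside
    the itemized error list.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return SimConfig(), AnalysisConfig(), ["config root must be a mapping"]
    sim_kwargs = {k: v for k, v in raw.get("simulation", {}).items()}
    ana_kwargs = {k: v for k, v in raw.get("analysis", {}).items()}
    for k in set(sim_kwargs) - _SIM_KEYS:
        errors.append(f"unknown simulation key: {k}")
        sim_kwargs.pop(k)
    for k in set(ana_kwargs) - _ANA_KEYS:
        errors.append(f"unknown analysis key: {k}")
        ana_kwargs.pop(k)
    for k in set(raw) - {"simulation", "analysis"}:
        errors.append(f"unknown top-level section: {k}")
    try:
        sim = SimConfig(**_coerce_tuples(sim_kwargs)).validate()
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        sim = SimConfig()
    try:
        ana = AnalysisConfig(**_coerce_tuples(ana_kwargs)).validate()
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        ana = AnalysisConfig()
    if sim.sfreq_raw <= 2 * ana.lowpass_broad and "simulation" in raw:
        # broad low-pass must stay below Nyquist of the raw rate
        if ana.lowpass_broad >= sim.sfreq_raw / 2:
            errors.append(
                f"lowpass_broad {ana.lowpass_broad} Hz >= Nyquist "
                f"({sim.sfreq_raw / 2} Hz) at sfreq_raw {sim.sfreq_raw}"
            )
    return sim, ana, errors
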