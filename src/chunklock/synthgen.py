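"""Synthetic MEG dataset generator with known ground truth.

The generative model per trial: an ongoing delta-band oscillator
``A·cos(2π·f·t + φ)`` whose phase is uniform before the chunk boundary and
is redrawn at t = 0 from a von Mises distribution whose concentration κ
depends on the duration level — phase reset with amplitude continuity.
Optionally an additive evoked component (a smooth kernel peaking ~0.3 s
after the boundary) is included, so that phase-reset and evoked-response
mechanisms for a boundary-locked deflection can be dissociated. The source
signal is projected to magnetometers through a mixing matrix derived from
three dipoles (left temporal, right temporal, right frontal) in a single
sphere model, and 1/f^α channel noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import EpochSet
from .forward import dipole_field
from .geometry import Sphere, toy_sensor_layout

__all__ = [
    "GroundTruth",
    "mixing_matrix",
    "generate_session",
    "generate_epochs",
    "generate_behavior",
    "generate_nback",
    "expected_itpc",
]

# Dipole positions (m) and tangential moments for the source topology:
# bilateral posterior temporal plus a right frontal generator.
DIPOLE_POSITIONS = np.array(
    [
        [-0.055, 0.000, 0.040],
        [0.055, 0.000, 0.040],
        [0.045, 0.050, 0.040],
    ]
)
DIPOLE_MOMENTS = np.array(
    [
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [-0.6, 0.8, 0.0],
    ]
)
DIPOLE_GAINS = np.array([1.0, 1.0, 0.8])


@dataclass
class GroundTruth:
    """Generative quantities aligned one-to-one with the produced trials."""

    phi_pre: np.ndarray  # per-trial pre-boundary phase (rad)
    theta: np.ndarray  # per-trial reset phase drawn at the boundary (rad)
    target_phase: float  # participant's mean reset phase (rad)
    mixing: np.ndarray  # channels x sources mixing matrix (T per unit signal)
    behavior_slopes: tuple[float, float]
    group_labels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"phi_pre": self.phi_pre, "theta": self.theta})


def expected_itpc(kappa: np.ndarray | float) -> np.ndarray | float:
    """Population ITPC of von Mises phases: I1(kappa)/I0(kappa)."""
    from scipy.special import i0e, i1e

    return i1e(kappa) / i0e(kappa)


def mixing_matrix(config: SimConfig, sphere: Sphere | None = None) -> np.ndarray:
    """Channels x 3 mixing matrix from the three fixed dipoles.

    Each dipole's sensor pattern is normalised to unit peak and scaled by
    its gain; the caller multiplies by the oscillator amplitude in tesla.
    """
    if sphere is None:
        sphere = Sphere()
    sensors = toy_sensor_layout(config.n_channels)
    cols = []
    for pos, mom, gain in zip(DIPOLE_POSITIONS, DIPOLE_MOMENTS, DIPOLE_GAINS):
        B = dipole_field(pos, mom, sensors.positions, sphere.center)
        pattern = np.einsum("ij,ij->i", B, sensors.orientations)
        cols.append(gain * pattern / np.max(np.abs(pattern)))
    return np.column_stack(cols)


def _participant_rng(config: SimConfig, participant: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(participant,))
    )


def _evoked_kernel(t: np.ndarray) -> np.ndarray:
    """Fixed smooth unimodal kernel peaking 0.3 s after the boundary."""
    g = np.exp(-((t - 0.3) ** 2) / (2 * 0.1**2))
    g[t < 0] = 0.0
    return g


def _one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq: float,
    exponent: float,
    scale: float,
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^alpha, SD = scale per channel."""
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_samples))
    spec = rfft(white, n=n_fft, axis=1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sfreq)
    f_min = 0.1  # Hz floor: flatten the spectrum below to avoid DC blow-up
    shaping = np.maximum(freqs, f_min) ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = irfft(spec * shaping, n=n_fft, axis=1)[:, :n_samples]
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * shaped / sd


def _trial_layout(config: SimConfig) -> tuple[int, int, int]:
    """Samples (pre, post, total) of one trial block including padding."""
    pre = int(round((-config.epoch_window[0] + config.pad) * config.sfreq_raw))
    post = int(round((config.epoch_window[1] + config.pad) * config.sfreq_raw))
    return pre, post, pre + post


def _block_labels(n_trials: int) -> np.ndarray:
    """Six recording blocks: 30 trials in the first five, remainder in the last."""
    per_block = max(1, int(np.ceil(n_trials / 6)))
    return np.minimum(np.arange(n_trials) // per_block, 5) + 1


def generate_session(
    config: SimConfig, participant: int
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, GroundTruth]:
    """Continuous multichannel recording with boundary events for one participant.

    Returns ``(signal, events, metadata, ground_truth)`` where ``signal`` is
    (channels, samples) at ``sfreq_raw``, ``events`` are the boundary sample
    indices and ``metadata`` has one row per trial (participant, trial,
    level, block, duration).
    """
    config.validate()
    rng = _participant_rng(config, participant)
    if config.target_phase is None:
        target = float(rng.uniform(-np.pi, np.pi))
    else:
        target = float(config.target_phase)

    n_levels = config.n_levels
    n_trials = n_levels * config.n_trials_per_level
    levels = np.repeat(np.arange(1, n_levels + 1), config.n_trials_per_level)
    rng.shuffle(levels)

    kappas = np.asarray(config.kappa_by_level)[levels - 1]
    phi_pre = rng.uniform(-np.pi, np.pi, size=n_trials)
    theta = np.where(
        kappas > 0, rng.vonmises(target, np.maximum(kappas, 1e-12)),
        rng.uniform(-np.pi, np.pi, size=n_trials),
    )

    means = np.array([m for m, _ in config.level_duration_mean_sd])[levels - 1]
    sds = np.array([s for _, s in config.level_duration_mean_sd])[levels - 1]
    durations = rng.normal(means, sds)

    pre, post, n_block = _trial_layout(config)
    t_rel = (np.arange(n_block) - pre) / config.sfreq_raw
    omega = 2 * np.pi * config.delta_freq
    # phase per trial/sample: uniform pre-boundary phase, reset draw at t=0
    phase = omega * t_rel[None, :] + np.where(
        t_rel[None, :] < 0, phi_pre[:, None], theta[:, None]
    )
    source = np.cos(phase)
    if config.evoked_gain != 0.0:
        source = source + config.evoked_gain * _evoked_kernel(t_rel)[None, :]
    # raised-cosine taper over the padding so block joins are continuous
    n_pad = max(1, int(round(config.pad * config.sfreq_raw)))
    window = np.ones(n_block)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_pad) / n_pad))
    window[:n_pad] = ramp
    window[-n_pad:] = ramp[::-1]
    source *= window[None, :]

    mix = mixing_matrix(config)  # channels x 3, gains already applied
    # the three dipoles carry the same boundary oscillator; normalise so the
    # strongest channel sees an oscillation of amplitude osc_amp
    pattern = mix.sum(axis=1)
    pattern = config.osc_amp * pattern / np.max(np.abs(pattern))

    n_total = n_trials * n_block
    signal = np.einsum("c,ts->cts", pattern, source).reshape(
        len(pattern), n_total
    )
    if config.noise_scale > 0:
        signal = signal + _one_over_f_noise(
            rng,
            config.n_channels,
            n_total,
            config.sfreq_raw,
            config.noise_exponent,
            config.noise_scale,
        )

    events = pre + n_block * np.arange(n_trials)
    metadata = pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n_trials),
            "level": levels,
            "block": _block_labels(n_trials),
            "duration": durations,
        }
    )
    gt = GroundTruth(
        phi_pre=phi_pre,
        theta=theta,
        target_phase=target,
        mixing=config.osc_amp * mix,
        behavior_slopes=tuple(config.behavior_slopes),
    )
    return signal, events, metadata, gt


def generate_epochs(
    config: SimConfig, participant: int
) -> tuple[EpochSet, GroundTruth]:
    """Raw (unfiltered) epochs around the boundary for one participant."""
    signal, events, metadata, gt = generate_session(config, participant)
    lo = int(round(config.epoch_window[0] * config.sfreq_raw))
    hi = int(round(config.epoch_window[1] * config.sfreq_raw))
    idx = events[:, None] + np.arange(lo, hi)[None, :]
    data = signal[:, idx].transpose(1, 0, 2)
    times = np.arange(lo, hi) / config.sfreq_raw
    return EpochSet(data=data, sfreq=config.sfreq_raw, times=times, metadata=metadata), gt


def _logit_slope_calibration(sigma_b: float, n_mc: int = 20001) -> float:
    """E[p(1-p)] under logistic with N(0, sigma_b^2) intercepts.

    Used to place the generative logit slope so that the *linear* effect of
    the centred ITPC feature on response probability equals the configured
    slope on the proportion scale.
    """
    from scipy.stats import norm

    q = norm.ppf(np.linspace(0.5 / n_mc, 1 - 0.5 / n_mc, n_mc)) * sigma_b
    p = 1.0 / (1.0 + np.exp(-q))
    return float(np.mean(p * (1 - p)))


def generate_behavior(
    config: SimConfig,
    itpc_feature: np.ndarray,
    groups: np.ndarray,
    trials: pd.DataFrame | None = None,
    intercept_sd: float = 0.4,
) -> pd.DataFrame:
    """Per-trial NP1/NP2 attachment responses driven by an ITPC feature.

    ``itpc_feature`` is (participants, levels) in [0, 1]; ``groups`` is a
    per-participant array of 'low'/'high' working-memory labels. Responses
    follow a random-intercept logistic model whose group-specific slope is
    calibrated so the implied *linear* effect on the response proportion
    equals ``config.behavior_slopes``. Timeouts occur at
    ``config.timeout_rate`` and are encoded as the string 'timeout'.

    ``trials`` (columns participant, level, trial) aligns responses with an
    existing trial table (e.g. the simulated session metadata); when
    omitted, a full participants x levels x n_trials_per_level crossing is
    generated.
    """
    itpc_feature = np.asarray(itpc_feature, dtype=float)
    if itpc_feature.min() < 0 or itpc_feature.max() > 1:
        raise ValueError("itpc_feature must lie in [0, 1]")
    groups = np.asarray(groups)
    bad = set(np.unique(groups)) - {"low", "high"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    n_part, n_levels = itpc_feature.shape
    if len(groups) != n_part:
        raise ValueError("groups must have one label per participant")

    if trials is None:
        p_idx, lv_idx, t_idx = np.meshgrid(
            np.arange(n_part),
            np.arange(1, n_levels + 1),
            np.arange(config.n_trials_per_level),
            indexing="ij",
        )
        trials = pd.DataFrame(
            {
                "participant": p_idx.ravel(),
                "level": lv_idx.ravel(),
                "trial": t_idx.ravel(),
            }
        )
    p_arr = trials["participant"].to_numpy()
    lv_arr = trials["level"].to_numpy()

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,))
    )
    slope_low, slope_high = config.behavior_slopes
    deriv = _logit_slope_calibration(intercept_sd)
    slope_by_part = np.where(
        groups == "low", slope_low / deriv, slope_high / deriv
    )

    centred = itpc_feature - itpc_feature.mean()
    b0 = rng.normal(0.0, intercept_sd, size=n_part)
    eta = b0[p_arr] + slope_by_part[p_arr] * centred[p_arr, lv_arr - 1]
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = rng.random(len(trials)) < prob
    timeout = rng.random(len(trials)) < config.timeout_rate
    response = np.where(timeout, "timeout", np.where(y, "NP2", "NP1"))
    return pd.DataFrame(
        {
            "participant": p_arr,
            "level": lv_arr,
            "trial": trials["trial"].to_numpy(),
            "response": response,
        }
    )


def generate_nback(
    config: SimConfig,
    ability_mean: float = 0.78,
    ability_sd: float = 0.12,
    fa_rate: float = 0.04,
    incomplete_rate: float = 3.0 / 40.0,
) -> pd.DataFrame:
    """Simulated n-back task: loads 2/3/4, three blocks each, six targets.

    Each block has 20 + n items of which six are targets. A participant's
    hit probability declines with load; a small fraction abandons the task
    part-way, in which case all remaining targets count as misses. Returns
    one row per (participant, load, block) with hit/false-alarm counts.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(20_000,))
    )
    loads = [2, 3, 4]
    rows = []
    for p in range(config.n_participants):
        ability = np.clip(rng.normal(ability_mean, ability_sd), 0.05, 0.995)
        incomplete = rng.random() < incomplete_rate
        # participants who stop do so somewhere in the final (4-back) blocks
        stop_block = rng.integers(0, 3) if incomplete else None
        for load in loads:
            n_items = 20 + load
            targets, nontargets = 6, n_items - 6
            hit_p = np.clip(ability - 0.08 * (load - 2), 0.0, 1.0)
            for b in range(3):
                aborted = incomplete and load == 4 and b >= stop_block
                if aborted:
                    hits = 0
                    fas = 0
                else:
                    hits = int(rng.binomial(targets, hit_p))
                    fas = int(rng.binomial(nontargets, fa_rate))
                rows.append((p, load, b + 1, hits, fas, targets, nontargets, aborted))
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "load",
            "block",
            "hits",
            "false_alarms",
            "targets",
            "nontargets",
            "aborted",
        ],
    )
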