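"""Per-cell association between evoked-field amplitude and phase coherence.

Within the cells (magnetometer x time point) of an observed ITPC cluster,
the evoked-field amplitude is regressed on ITPC with a linear mixed-effects
model: ITPC as fixed effect, random intercepts for participants, fitted by
maximum likelihood. The p-value comes from a likelihood-ratio chi^2(1) test
against the intercept-only model (random intercepts retained); within a
cluster, p-values are Bonferroni-corrected across its cells. Only the
magnitude of the deviation from zero is interpreted — the sign of a
magnetometer slope reflects dipole orientation, not effect direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cluster import Cluster
from .phase import ERFMap, ITPCMap

__all__ = [
    "LinkFit",
    "fit_amplitude_itpc",
    "bonferroni_mask",
    "extract_cluster_cells",
    "link_cluster",
]


@dataclass
class LinkFit:
    slope: float
    t_value: float
    p_lrt: float
    pooled_fallback: bool = False


def _pooled_fit(amplitude: np.ndarray, itpc: np.ndarray) -> LinkFit:
    import statsmodels.api as sm

    X = sm.add_constant(itpc)
    ols = sm.OLS(amplitude, X).fit()
    null = sm.OLS(amplitude, np.ones_like(amplitude)).fit()
    lrt = 2 * (ols.llf - null.llf)
    return LinkFit(
        slope=float(ols.params[1]),
        t_value=float(ols.tvalues[1]),
        p_lrt=float(chi2.sf(max(lrt, 0.0), df=1)),
        pooled_fallback=True,
    )


def fit_amplitude_itpc(
    amplitude: np.ndarray, itpc: np.ndarray, participants: np.ndarray
) -> LinkFit:
    """Random-intercept LMM of amplitude on ITPC, ML fit, LRT p-value.

    All three arrays are flat and aligned (participant-level pairs across
    duration levels). If the between-participant variance collapses to
    zero (singular fit), falls back to a pooled OLS regression, flagged in
    the result.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    amplitude = np.asarray(amplitude, dtype=float).ravel()
    itpc = np.asarray(itpc, dtype=float).ravel()
    participants = np.asarray(participants).ravel()
    if not (len(amplitude) == len(itpc) == len(participants)):
        raise ValueError("amplitude, itpc and participants must be aligned")
    counts = pd.Series(participants).value_counts()
    if (counts < 2).any():
        raise ValueError("every participant needs >= 2 paired observations")

    exog = np.column_stack([np.ones_like(itpc), itpc])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = MixedLM(amplitude, exog, groups=participants).fit(reml=False)
            null = MixedLM(
                amplitude, exog[:, :1], groups=participants
            ).fit(reml=False)
        except Exception:
            return _pooled_fit(amplitude, itpc)
    if not np.isfinite(full.llf) or not np.isfinite(null.llf):
        return _pooled_fit(amplitude, itpc)
    if float(np.asarray(full.cov_re)[0, 0]) < 1e-12 * max(
        float(np.var(amplitude)), 1e-300
    ):
        return _pooled_fit(amplitude, itpc)
    lrt = 2 * (full.llf - null.llf)
    return LinkFit(
        slope=float(full.fe_params[1]),
        t_value=float(full.fe_params[1] / full.bse_fe[1]),
        p_lrt=float(chi2.sf(max(lrt, 0.0), df=1)),
    )


def bonferroni_mask(p_values: np.ndarray, m: int | None = None, alpha: float = 0.05) -> np.ndarray:
    """Boolean significance mask after Bonferroni correction over m cells."""
    p_values = np.asarray(p_values, dtype=float)
    if m is None:
        m = p_values.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p_values * m < alpha


def extract_cluster_cells(
    value_map: ITPCMap | ERFMap, cluster: Cluster
) -> pd.DataFrame:
    """Aligned (participant, level) value pairs for every cell of a cluster.

    Returns a long DataFrame with columns participant, level, channel,
    time_index, value — one row per participant x level x cluster cell.
    """
    if len(cluster.cells) == 0:
        raise ValueError("empty cluster")
    vals = value_map.values  # (P, L, C, T)
    P, L, C, T = vals.shape
    ch = cluster.cells[:, 0]
    ti = cluster.cells[:, 1]
    if ch.max() >= C or ti.max() >= T:
        raise ValueError("cluster cells outside the map support")
    sub = vals[:, :, ch, ti]  # (P, L, k)
    parts = np.repeat(value_map.participants, L * len(ch))
    levels = np.tile(np.repeat(value_map.levels, len(ch)), P)
    chans = np.tile(ch, P * L)
    times = np.tile(ti, P * L)
    return pd.DataFrame(
        {
            "participant": parts,
            "level": levels,
            "channel": chans,
            "time_index": times,
            "value": sub.ravel(),
        }
    )


def link_cluster(
    erf_map: ERFMap,
    itpc_map: ITPCMap,
    cluster: Cluster,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the amplitude~ITPC mixed model at every cell of an ITPC cluster.

    Returns one row per cell with slope, t, LRT p, Bonferroni-corrected
    significance (m = number of cells in the cluster), and fallback flag.
    """
    amp = extract_cluster_cells(erf_map, cluster)
    coh = extract_cluster_cells(itpc_map, cluster)
    rows = []
    m = len(cluster.cells)
    for (ch, ti), amp_grp in amp.groupby(["channel", "time_index"], sort=True):
        coh_grp = coh[(coh["channel"] == ch) & (coh["time_index"] == ti)]
        fit = fit_amplitude_itpc(
            amp_grp["value"].to_numpy(),
            coh_grp["value"].to_numpy(),
            amp_grp["participant"].to_numpy(),
        )
        rows.append(
            {
                "channel": ch,
                "time_index": ti,
                "slope": fit.slope,
                "t_value": fit.t_value,
                "p_lrt": fit.p_lrt,
                "pooled_fallback": fit.pooled_fallback,
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = bonferroni_mask(table["p_lrt"].to_numpy(), m, alpha)
    return table
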