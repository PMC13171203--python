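"""Behavioral pipeline: n-back scoring, median split, and attachment models.

Attachment of the ambiguous relative clause (NP1 = high, NP2 = low) is
modelled two ways: a single-trial binomial GLMM with the ordered duration
level as fixed effect (polynomial contrasts) and random intercepts for
participants, tested by likelihood ratio against the intercept-only model
(df = n_levels - 1); and a linear mixed model of the per-level NP2
proportion on the ITPC feature, working-memory group (sum contrast-coded)
and their interaction, with forward stepwise term selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import glmm

__all__ = [
    "nback_score",
    "score_participants",
    "median_split",
    "glmm_attachment_level",
    "attachment_itpc_interaction",
    "attachment_proportions",
    "InteractionFit",
]


def nback_score(
    hits, targets, false_alarms, nontargets, incomplete: bool = False
) -> float:
    """Working-memory score: hit proportion minus false-alarm proportion.

    Accepts scalars or per-block sequences; totals are pooled before the
    proportions are formed. ``incomplete`` marks that unanswered blocks
    were already scored with their remaining targets as misses (hits = 0
    for those blocks) — the counts are used as given.
    """
    hits = np.atleast_1d(np.asarray(hits, dtype=float))
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    fas = np.atleast_1d(np.asarray(false_alarms, dtype=float))
    nontargets = np.atleast_1d(np.asarray(nontargets, dtype=float))
    if np.any(hits > targets):
        raise ValueError("hits cannot exceed targets")
    if np.any(fas > nontargets):
        raise ValueError("false alarms cannot exceed nontargets")
    return float(hits.sum() / targets.sum() - fas.sum() / nontargets.sum())


def score_participants(nback_table: pd.DataFrame) -> pd.Series:
    """Per-participant n-back scores from a block-level count table."""
    def _score(grp: pd.DataFrame) -> float:
        return nback_score(
            grp["hits"], grp["targets"], grp["false_alarms"], grp["nontargets"],
            incomplete=bool(grp.get("aborted", pd.Series(False)).any()),
        )

    return nback_table.groupby("participant").apply(_score, include_groups=False)


def median_split(scores: pd.Series | np.ndarray) -> np.ndarray:
    """'low' for scores <= median, 'high' above; deterministic tie rule.

    With an even number of distinct scores this reproduces an equal split.
    All-equal scores admit no split and are rejected.
    """
    values = np.asarray(scores, dtype=float)
    if len(values) < 2:
        raise ValueError("median split needs >= 2 participants")
    if np.all(values == values[0]):
        raise ValueError("all scores equal; no median split possible")
    med = np.median(values)
    return np.where(values <= med, "low", "high")


def _poly_contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix (n_levels x (n_levels-1))."""
    x = np.arange(1, n_levels + 1, dtype=float)
    V = np.vander(x, n_levels, increasing=True)
    Q, _ = np.linalg.qr(V)
    Q = Q[:, 1:]  # drop the constant column
    # fix signs so the linear contrast increases with level
    for j in range(Q.shape[1]):
        if Q[-1, j] < 0 and j == 0:
            Q[:, j] *= -1
    return Q


def glmm_attachment_level(
    table: pd.DataFrame, contrasts: str = "poly"
) -> dict:
    """Binomial GLMM of single-trial NP2 response on ordered level.

    Timeouts are removed first. Returns the likelihood-ratio chi^2 against
    the intercept-only model (random intercepts retained), df =
    n_levels - 1, and the p-value.
    """
    kept = table[table["response"] != "timeout"]
    levels = np.sort(kept["level"].unique())
    n_levels = len(levels)
    if n_levels < 2:
        raise ValueError("need >= 2 levels represented")
    y = (kept["response"] == "NP2").to_numpy(float)
    groups = kept["participant"].to_numpy()
    level_idx = np.searchsorted(levels, kept["level"].to_numpy())
    if contrasts == "poly":
        C = _poly_contrasts(n_levels)
    elif contrasts == "dummy":
        C = np.eye(n_levels)[:, 1:]
    else:
        raise ValueError(f"unknown contrasts {contrasts!r}")
    X_full = np.column_stack([np.ones(len(y)), C[level_idx]])
    X_null = np.ones((len(y), 1))
    full = glmm.fit_logistic_ri(y, X_full, groups)
    null = glmm.fit_logistic_ri(y, X_null, groups)
    df = n_levels - 1
    stat, p = glmm.lrt(full, null, df)
    if full.separation:
        warnings.warn("quasi-complete separation; penalized fit used",
                      stacklevel=2)
    return {
        "chi2": stat,
        "df": df,
        "p": p,
        "full": full,
        "null": null,
    }


def attachment_proportions(
    table: pd.DataFrame, exclude_trials: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per participant x level proportion of NP2 (low-attachment) responses.

    ``exclude_trials`` (columns participant, trial) removes trials that
    were dropped from the MEG analysis before the proportion is formed;
    timeouts are always removed.
    """
    kept = table[table["response"] != "timeout"]
    if exclude_trials is not None and len(exclude_trials):
        key = set(zip(exclude_trials["participant"], exclude_trials["trial"]))
        mask = [
            (p, t) not in key
            for p, t in zip(kept["participant"], kept["trial"])
        ]
        kept = kept[np.asarray(mask)]
    out = (
        kept.assign(np2=(kept["response"] == "NP2").astype(float))
        .groupby(["participant", "level"])["np2"]
        .mean()
        .reset_index(name="prop_np2")
    )
    return out


@dataclass
class InteractionFit:
    """Result of the attachment ~ ITPC x group linear mixed model."""

    terms: list[str]
    estimates: dict = field(default_factory=dict)
    t_values: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    slope_low: float | None = None
    slope_high: float | None = None
    interaction_p: float | None = None


def _mixedlm(endog, exog, groups):
    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MixedLM(endog, exog, groups=groups).fit(reml=False)


def attachment_itpc_interaction(
    prop_np2: np.ndarray,
    itpc_feature: np.ndarray,
    group: np.ndarray,
    select: bool = True,
    entry_alpha: float = 0.05,
) -> InteractionFit:
    """LMM of NP2 proportion on ITPC, group (sum-coded) and their interaction.

    All three inputs are aligned per (participant, level) cell: ``prop_np2``
    and ``itpc_feature`` are (participants, levels); ``group`` is one
    'low'/'high' label per participant. Sum coding assigns low = +1,
    high = -1, so the per-group simple slopes are beta_itpc +/- beta_int.

    With ``select=True`` terms enter forward stepwise by likelihood-ratio
    improvement (main effects first; the interaction is tested on top of
    both main effects, which are retained for marginality if it enters).
    With ``select=False`` the full model is fitted directly.
    """
    prop = np.asarray(prop_np2, dtype=float)
    feat = np.asarray(itpc_feature, dtype=float)
    group = np.asarray(group)
    P, L = prop.shape
    for g in ("low", "high"):
        if np.sum(group == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
    gcode = np.where(group == "low", 1.0, -1.0)

    part = np.repeat(np.arange(P), L)
    y = prop.ravel()
    x_itpc = feat.ravel()
    x_g = np.repeat(gcode, L)
    x_int = x_itpc * x_g
    columns = {"itpc": x_itpc, "group": x_g, "itpc:group": x_int}

    def fit_terms(terms: list[str]):
        X = np.column_stack(
            [np.ones_like(y)] + [columns[t] for t in terms]
        )
        return _mixedlm(y, X, part), X

    if not select:
        chosen = ["itpc", "group", "itpc:group"]
    else:
        chosen = []
        base, _ = fit_terms(chosen)
        # stage 1: main effects, best-first
        candidates = ["itpc", "group"]
        while candidates:
            trials = []
            for term in candidates:
                m, _ = fit_terms(chosen + [term])
                stat = max(0.0, 2 * (m.llf - base.llf))
                trials.append((float(chi2.sf(stat, 1)), term, m))
            trials.sort()
            p_best, term_best, m_best = trials[0]
            if p_best < entry_alpha:
                chosen.append(term_best)
                base = m_best
                candidates.remove(term_best)
            else:
                break
        # stage 2: interaction on top of both mains (marginality respected)
        mains_model, _ = fit_terms(["itpc", "group"])
        int_model, _ = fit_terms(["itpc", "group", "itpc:group"])
        stat = max(0.0, 2 * (int_model.llf - mains_model.llf))
        p_int = float(chi2.sf(stat, 1))
        if p_int < entry_alpha:
            chosen = ["itpc", "group", "itpc:group"]

    model, X = fit_terms(chosen)
    names = ["intercept"] + chosen
    est = {n: float(model.fe_params[i]) for i, n in enumerate(names)}
    tv = {n: float(model.fe_params[i] / model.bse_fe[i]) for i, n in enumerate(names)}
    pv = {n: float(model.pvalues[i]) for i, n in enumerate(names)}

    fit = InteractionFit(terms=chosen, estimates=est, t_values=tv, p_values=pv)
    if "itpc:group" in chosen:
        b1 = est.get("itpc", 0.0)
        b3 = est["itpc:group"]
        fit.slope_low = b1 + b3
        fit.slope_high = b1 - b3
        fit.interaction_p = pv["itpc:group"]
    return fit
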