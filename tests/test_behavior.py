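"""n-back scoring, median split, attachment GLMM and interaction LMM."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from chunklock import glmm
from chunklock.behavior import (
    attachment_itpc_interaction,
    attachment_proportions,
    glmm_attachment_level,
    median_split,
    nback_score,
)
from chunklock.config import SimConfig
from chunklock.synthgen import generate_behavior


# -------------------------------------------------------------- n-back


def test_perfect_responder_scores_one():
    assert nback_score(6, 6, 0, 16) == 1.0
    hits = [6] * 9
    targets = [6] * 9
    fas = [0] * 9
    nontargets = [16, 16, 16, 17, 17, 17, 18, 18, 18]
    assert nback_score(hits, targets, fas, nontargets) == 1.0


def test_never_pressing_scores_zero():
    assert nback_score(0, 6, 0, 16) == 0.0


def test_single_block_arithmetic():
    """2-back block: 22 items, 6 targets, 16 nontargets; 5 hits, 1 FA."""
    assert nback_score(5, 6, 1, 16) == pytest.approx(5 / 6 - 1 / 16, abs=1e-10)
    assert nback_score(5, 6, 1, 16) == pytest.approx(0.7708, abs=5e-5)


def test_incomplete_equals_remaining_targets_missed():
    """Scoring an aborted final block is identical to counting its targets
    as misses (hits = 0 for that block)."""
    complete = nback_score([6, 6, 0], [6, 6, 6], [1, 0, 0], [16, 16, 16])
    as_missed = nback_score(
        [6, 6, 0], [6, 6, 6], [1, 0, 0], [16, 16, 16], incomplete=True
    )
    assert complete == as_missed


def test_hits_exceed_targets_rejected():
    with pytest.raises(ValueError, match="exceed"):
        nback_score(7, 6, 0, 16)


# -------------------------------------------------------- median split


def test_median_split_40_distinct_is_20_20(rng):
    scores = rng.permutation(np.linspace(-0.5, 1.0, 40))
    labels = median_split(scores)
    assert np.sum(labels == "low") == 20
    assert np.sum(labels == "high") == 20
    low_scores = scores[labels == "low"]
    assert low_scores.max() < scores[labels == "high"].min()


def test_median_split_tie_rule():
    labels = median_split(np.array([0.0, 0.0, 1.0, 1.0]))
    assert labels.tolist() == ["low", "low", "high", "high"]


def test_median_split_order_invariant(rng):
    scores = rng.normal(size=15)
    labels = median_split(scores)
    perm = rng.permutation(15)
    assert np.array_equal(median_split(scores[perm]), labels[perm])


def test_median_split_degenerate_rejected():
    with pytest.raises(ValueError, match="equal"):
        median_split(np.ones(10))


# ------------------------------------------------------------ level GLMM


def _behavior_table(rng, n_part=10, n_trials=5, level_effect=0.0):
    rows = []
    b0 = rng.normal(0, 0.5, n_part)
    for p in range(n_part):
        for lv in range(1, 8):
            eta = b0[p] + level_effect * (lv - 4)
            y = rng.random(n_trials) < 1 / (1 + np.exp(-eta))
            for t, yi in enumerate(y):
                rows.append((p, lv, t, "NP2" if yi else "NP1"))
    return pd.DataFrame(rows, columns=["participant", "level", "trial", "response"])


def test_glmm_df_is_levels_minus_one(rng):
    table = _behavior_table(rng)
    res = glmm_attachment_level(table)
    assert res["df"] == 6


def test_glmm_detects_strong_level_effect(rng):
    table = _behavior_table(rng, n_part=20, n_trials=15, level_effect=0.5)
    res = glmm_attachment_level(table)
    assert res["p"] < 0.001


def test_glmm_null_moderate_p(rng):
    table = _behavior_table(rng, n_part=15, n_trials=10, level_effect=0.0)
    res = glmm_attachment_level(table)
    assert res["p"] > 0.01


def test_glmm_matches_lme4_oracle(rng, tmp_path):
    """AGQ logistic GLMM agrees with lme4::glmer (nAGQ=15) on loglik/beta."""
    G, n = 10, 30
    b = rng.normal(0, 0.7, G)
    x = rng.normal(size=(G, n))
    eta = 0.3 + 0.5 * x + b[:, None]
    y = (rng.random((G, n)) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(G * n), x.ravel()])
    g = np.repeat(np.arange(G), n)
    fit = glmm.fit_logistic_ri(y.ravel(), X, g)

    csv = tmp_path / "dat.csv"
    np.savetxt(csv, np.column_stack([y.ravel(), x.ravel(), g]),
               delimiter=",", header="y,x,g", comments="")
    script = (
        f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
        "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15); "
        'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    vals = [float(v) for v in out.stdout.strip().splitlines()[-4:]]
    assert fit.beta[0] == pytest.approx(vals[0], abs=1e-3)
    assert fit.beta[1] == pytest.approx(vals[1], abs=1e-3)
    assert fit.sigma == pytest.approx(vals[2], abs=1e-3)
    assert fit.loglik == pytest.approx(vals[3], abs=1e-3)


def test_timeouts_removed_before_fitting(rng):
    table = _behavior_table(rng)
    with_timeouts = pd.concat(
        [
            table,
            pd.DataFrame(
                {
                    "participant": [0, 1],
                    "level": [1, 2],
                    "trial": [99, 99],
                    "response": ["timeout", "timeout"],
                }
            ),
        ],
        ignore_index=True,
    )
    a = glmm_attachment_level(table)
    b = glmm_attachment_level(with_timeouts)
    assert a["chi2"] == pytest.approx(b["chi2"], abs=1e-6)


# ------------------------------------------------- interaction LMM


def _interaction_data(rng, slope_low=0.11, slope_high=-0.10, P=40, noise=0.02):
    feat = np.clip(
        np.linspace(0.1, 0.8, 7)[None, :] + rng.normal(0, 0.05, (P, 7)), 0, 1
    )
    groups = np.array(["low"] * (P // 2) + ["high"] * (P // 2))
    slopes = np.where(groups == "low", slope_low, slope_high)
    centred = feat - feat.mean()
    base = 0.5 + rng.normal(0, 0.05, P)
    prop = np.clip(
        base[:, None] + slopes[:, None] * centred + rng.normal(0, noise, (P, 7)),
        0,
        1,
    )
    return prop, feat, groups


def test_sum_coding_symmetry(rng):
    """Swapping group labels flips the interaction sign only."""
    prop, feat, groups = _interaction_data(rng)
    fit1 = attachment_itpc_interaction(prop, feat, groups, select=False)
    swapped = np.where(groups == "low", "high", "low")
    fit2 = attachment_itpc_interaction(prop, feat, swapped, select=False)
    assert fit1.estimates["itpc:group"] == pytest.approx(
        -fit2.estimates["itpc:group"], abs=1e-8
    )
    assert fit1.estimates["itpc"] == pytest.approx(fit2.estimates["itpc"], abs=1e-8)
    # the original low group is labeled high after the swap
    assert fit1.slope_low == pytest.approx(fit2.slope_high, abs=1e-8)


def test_interaction_recovers_group_slopes(rng):
    prop, feat, groups = _interaction_data(rng)
    fit = attachment_itpc_interaction(prop, feat, groups, select=False)
    assert fit.slope_low == pytest.approx(0.11, abs=0.04)
    assert fit.slope_high == pytest.approx(-0.10, abs=0.04)


def test_selection_keeps_interaction_when_real(rng):
    prop, feat, groups = _interaction_data(rng, noise=0.01)
    fit = attachment_itpc_interaction(prop, feat, groups, select=True)
    assert "itpc:group" in fit.terms
    assert fit.interaction_p < 0.05


def test_selection_drops_null_interaction():
    hits = 0
    reps = 20
    for r in range(reps):
        rng = np.random.default_rng(1000 + r)
        prop, feat, groups = _interaction_data(
            rng, slope_low=0.0, slope_high=0.0, noise=0.05
        )
        fit = attachment_itpc_interaction(prop, feat, groups, select=True)
        if "itpc:group" in fit.terms:
            hits += 1
    assert hits <= 4  # ~alpha-level false inclusion


def test_group_size_validation(rng):
    prop, feat, groups = _interaction_data(rng, P=4)
    groups = np.array(["low", "low", "low", "high"])
    with pytest.raises(ValueError, match="fewer than 2"):
        attachment_itpc_interaction(prop, feat, groups)


def test_attachment_proportions_excludes_trials():
    cfg = SimConfig(n_participants=2, seed=3, timeout_rate=0.0)
    feat = np.full((2, 7), 0.5)
    tab = generate_behavior(cfg, feat, np.array(["low", "high"]))
    excl = tab[["participant", "trial"]].iloc[:5].assign(participant=0)
    props_all = attachment_proportions(tab)
    props_excl = attachment_proportions(tab, exclude_trials=excl)
    n_all = len(tab[tab["participant"] == 0])
    # the exclusion removes exactly those trials from participant 0's cells
    assert props_all.shape == props_excl.shape
    assert not props_all["prop_np2"].equals(props_excl["prop_np2"])
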