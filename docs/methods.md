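# Methods

## The phenomenon being modelled

During auditory sentence comprehension, listeners group words into
multi-word chunks. Closing a chunk elicits a boundary-locked brain
response (the Closure Positive Shift in EEG), and chunk boundaries have
been associated with delta-band (<4 Hz) neural activity. The hypothesis
this package operationalises is that the boundary response arises from
*phase-locking* of ongoing low-frequency activity: at the moment a chunk
is closed, the phase of a slow oscillation is reset toward a preferred
angle, and the strength of that reset grows with the duration of the
chunk. Inter-trial phase coherence (ITPC) then increases with clause
duration, an "evoked" deflection appears in the trial average without any
additive response, and the two are statistically linked.

Because raw MEG recordings for this paradigm are not publicly available,
every analysis in the package runs on synthetic data with known ground
truth, and the claims tested are recovery and calibration claims: does
each analysis stage find what was put in, and nothing when nothing was
put in?

## Generative model

For each trial at duration level `L ∈ {1..7}` the source signal is

    s(t) = A · cos(2π f t + φ),   φ = φ_pre ~ Uniform(−π, π]   for t < 0
                                  φ = θ    ~ von Mises(μ_p, κ_L) for t ≥ 0

with the boundary at `t = 0`. The reset is an instantaneous redraw of the
phase with amplitude continuity — the simplest mechanism that dissociates
phase alignment from amplitude change. `κ_L` (the von Mises
concentration) is monotone non-decreasing in level; the population ITPC
of the reset phases is the Bessel ratio `I₁(κ)/I₀(κ)`, which all
recovery tests use as the analytic reference.

An optional additive evoked component `g(t)` (Gaussian kernel, peak
0.3 s post-boundary, SD 0.1 s) is available through `evoked_gain`
because the literature cannot currently distinguish a reset of ongoing
activity from a series of evoked responses; the simulator exposes both
mechanisms rather than asserting one.

The source drives three tangential dipoles (left posterior temporal,
right posterior temporal, right frontal — mirroring the reported source
topology) inside a homogeneous sphere (Sarvas closed form); their summed
sensor pattern is normalised so the strongest magnetometer carries an
oscillation of amplitude `osc_amp`. Channel noise is Gaussian with a
`1/f^α` power spectrum (α = 1), flattened below 0.1 Hz.

Key defaults, with units and rationale:

| parameter | default | why |
| --- | --- | --- |
| `n_participants` | 40 | study condition |
| `n_trials_per_level` | 25 (7 levels, 175 trials) | study condition |
| `sfreq_raw` | 1000 Hz | acquisition rate; exercises the decimation path |
| `delta_freq` | 1/2.7 Hz ≈ 0.37 Hz | one cycle per hypothesised 2.7 s integration window; configurable because only the band (<4 Hz) is pinned |
| `kappa_by_level` | linspace(0, 8, 7) | monotone reset profile spanning no locking (ITPC 0) to strong locking (ITPC ≈ 0.94) |
| `target_phase` | None (per-participant draw) | the preferred reset angle is a property of a participant's cortical geometry and dipole orientation; there is no reason for it to be shared across heads. This choice also reproduces the reported dissociation: ITPC is phase-invariant, while the group-level evoked field cancels across participants |
| `osc_amp` | 60 fT | realistic magnetometer-scale delta amplitude |
| `noise_scale` | 50 fT | in-band SNR near 1, keeping single-trial phase noisy but recoverable at 25 trials |
| `level_duration_mean_sd` | (2.09, 0.14) … (3.78, 0.16) s | the seven main-clause duration levels |
| `behavior_slopes` | (+0.11, −0.10) | proportion-scale ITPC→attachment slopes for low/high working-memory span |
| `timeout_rate` | 1/175 | about one timed-out response per participant |

Epochs are generated as a continuous per-participant recording (trial
blocks joined with raised-cosine amplitude tapers over the 0.6 s padding,
so filtering the concatenation introduces no join transients), with
boundary events marked, so the preprocessing path is exercised exactly as
it would be on a real recording.

Behavioral responses follow a random-intercept logistic model on the
per-trial NP2 (low attachment) choice. The configured slopes are on the
proportion scale; the generative logit slope is calibrated by dividing by
`E[p(1−p)]` under the intercept distribution, so the *linear* effect of
the centred ITPC feature on the response proportion equals the configured
value and the downstream linear mixed model recovers it without scale
juggling. The n-back generator simulates 2/3/4-back at three blocks each
(20 + n items, six targets per block) from a per-participant ability;
participants who abandon the task have all remaining targets scored as
misses.

## What the simulator does not emulate

No head movement, no sensor drift or SQUID jumps unless injected, no eye
or cardiac artifacts (the threshold rejection replaces ICA), no realistic
anatomy (a sphere instead of a boundary-element model), no inter-channel
noise correlation, and no linguistic content — levels differ only in
duration statistics and reset concentration. Passing tests therefore
show the *analysis chain* is correct and calibrated, not that the
scientific result would replicate on real recordings.

## Preprocessing

Two-pass (zero-phase) Butterworth IIR filters via second-order sections:
0.2 Hz high-pass (order 5) and 30 Hz low-pass (order 14) on the
continuous data; 6 s epochs (±3 s around the boundary); automatic
rejection; decimation to 100 Hz by integer stride anchored at t = 0; and
a 4 Hz low-pass (order 8) before phase extraction. Reflect padding of at
least 6× the filter order suppresses edge transients. The closed-form
squared-magnitude response (with the bilinear tan-prewarp, exact for the
digital design) is the oracle for all attenuation checks.

Artifact rejection has two rules. Amplitude: any channel exceeding
±5 pT. Jumps: the epoch's 9-sample median-filtered signal is differenced
and the absolute difference z-scored per channel against the pooled
mean/SD over the whole epoch set; any z > 60 rejects the epoch. The
difference step matters: a step discontinuity is an isolated extreme
*difference*, whereas the z-score of the raw median-filtered signal is
bounded by √n within an epoch and could never reach 60. The pooled
reference population is what makes a single jumpy epoch stand out against
hundreds of clean ones.

## Sensor statistics

ITPC at a cell (channel × time) is the resultant length
`|n⁻¹ Σ exp(iφ_j)|` across the 25 trials of a level, computed per
participant from the Hilbert analytic phase of the 4 Hz-low-passed
signal. No bias correction is applied: trial counts are equalised per
level by design, so the O(1/n) bias is common to all levels and cancels
in the level regression; counts are logged per cell regardless.

The level effect is tested with a cluster-based permutation regression:
per participant, the OLS slope of the cell value on level index 1..7;
a one-sample t over participants (df = 39 at full scale); supra-threshold
cells (parametric two-tailed t at p = 0.05 — the conventional default, as
the cluster-forming threshold is a free parameter of the framework)
merged through sensor adjacency at equal time plus temporal succession;
clusters spanning fewer than 3 distinct channels pruned ("at least 3
channels anywhere in the cluster"; a per-time-point variant is a flag);
cluster-sum t compared to the permutation null of the per-sign maximum
cluster sum under within-participant permutation of the 7 level labels.
P-values use the +1 convention, so p ≥ 1/(n_perm+1); two-sided
significance is assessed at α/2 = 0.025 per sign. The level *index* is
the predictor (duration-as-predictor is an option): levels are designed
orderings, and the index regression is what the cluster test permutes.

Sensor adjacency is distance-based (neighbours within 1.5× the median
nearest-neighbour spacing on the cap). The ERF regression is identical,
run on the broadband (0.2–30 Hz) trial averages.

## ERF ~ ITPC link

Within the cells of an observed ITPC cluster, a linear mixed model per
cell: amplitude ~ ITPC with random intercepts for participants, fitted by
maximum likelihood (ML rather than REML because the p-value comes from a
likelihood-ratio χ²(1) against the intercept-only model, and LRTs on
fixed effects require ML). Observations are per-participant per-level
cell values — the model is fitted across participants, not trials.
Bonferroni correction multiplies each p by the number of cells in its
cluster. A singular fit (between-participant variance collapsing to 0)
falls back to pooled OLS and is flagged. The delta-band variant re-uses
the 4 Hz-filtered 6 s epochs for the amplitude side. Slope signs are not
interpreted — a magnetometer's sign reflects dipole orientation — only
the deviation from zero.

## Source analysis

Leadfields come from the Sarvas single-sphere solution on a coarse grid
spanning the upper head volume (15 mm step; nodes outside the conductor
dropped, so edge nodes have fewer than the maximum 26 neighbours). The
LCMV spatial filter uses the sensor covariance pooled over all conditions
in the −0.85 to 1.38 s window, regularized as `C + λ·(tr C/n)·I` with
λ = 5% of mean sensor power. Per node the fixed orientation is the
principal axis of the reconstructed source covariance `(LᵀC'⁻¹L)⁻¹`
("axis of most variance"; a power-SVD alternative sits behind a flag),
solved in the leadfield's non-degenerate subspace because the radial
column vanishes on a sphere. Weights are unit-noise-gain normalised
(‖w‖ = 1) against depth bias. The filter is applied to the
Hilbert-transformed single trials (filter and Hilbert commute — asserted
to 1e-10); node ITPC is computed across trials pooled over recording
blocks (the block-wise reading of "across blocks" is not decidable;
trials-pooled is the default), averaged over 0.15–0.38 s, and tested
one-sided with the grid adjacency. Atlas parcellation is replaced by
configurable labeled node subsets.

The covariance window −0.85 to 1.38 s and the averaging window
0.15–0.38 s are used verbatim as stated, although the "±1 s around the
sensor clusters" derivation does not reproduce them arithmetically.

## Behavioral models

The n-back score is hits/targets − false alarms/nontargets pooled over
the nine blocks. The median split sends scores ≤ median to the low
group — deterministic, and exactly 20/20 for 40 distinct scores. The
single-trial attachment GLMM is a binomial random-intercept model with
the ordered factor level coded by orthonormal polynomial contrasts
(df = 6 for 7 levels; dummy coding behind a flag), fitted by adaptive
Gauss–Hermite quadrature (15 nodes, Laplace-centred per participant) and
tested by likelihood ratio against the intercept-only model. The AGQ
implementation reproduces lme4's `glmer(nAGQ = 15)` log-likelihood and
estimates to ~1e-3 on shared data (asserted in a test against Rscript).
Quasi-complete separation triggers a flagged ridge-penalized refit.

The attachment ~ ITPC × working-memory-group model is a linear mixed
model on the per-level NP2 proportion (trials excluded from the MEG
analysis and timeouts removed first), with ITPC numeric, group sum-coded
(low = +1, high = −1) and random intercepts. Term selection is forward
stepwise by LRT at α = 0.05: main effects first, then the interaction
tested on top of *both* main effects; if the interaction enters, the main
effects are retained for marginality even when individually
non-significant — which is how an interaction-only finding (no main
effects) remains reachable. The ITPC feature is taken at the single
(magnetometer, time) cell with the strongest positive and, separately,
strongest negative amplitude~ITPC t-value. Simple slopes are
`β_itpc ± β_interaction`.

## Numerical choices and degenerate inputs

- Exact-zero slope variance across participants (constant synthetic
  input) maps to t = 0 when the common slope is 0 and to a capped
  t = ±1e6 otherwise; the tolerance is relative (1e-12 of the cell's RMS)
  so floating-point round-off from constant data does not produce
  spurious infinities.
- Connected components run on a prebuilt sparse cell graph; the
  permutation loop recomputes the t map vectorised over permutation
  blocks sized to keep the slope array under ~80 MB.
- Degenerate von Mises draws (κ = 0) fall back to uniform sampling;
  κ → ∞ is numerically safe through the generator.
- The covariance of noiseless rank-deficient data triggers a warning and
  relies on the λ-regularization for invertibility; a condition number
  above 1e12 after regularization is rejected.
- Non-monotone κ profiles are allowed with a warning (used for null
  calibrations).

## Problem sizes in the validation studies

The repeated simulation studies (calibration, power, recovery) generate
epochs at the 100 Hz analysis rate with a ±1.3 s window; the statistics
are computed on the 0–1 s post-boundary window at 100 Hz either way, so
this skips only the raw-rate decimation, which the unit tests and the
acceptance script's pipeline run (raw rate 300 Hz, 40 participants,
7 × 25 trials, 24 channels) exercise separately. Calibration uses 200
null datasets (constant κ = 1) at 10 participants × 20 channels with 500
permutations; power uses 50 replicates at 40 participants with 200
permutations (the smallest resolvable p of 1/201 is well below the 0.025
criterion); link recovery uses 200 replicates; behavioral recovery 100.

## Known limitations

- The sphere conductor and radial magnetometers make radial sources
  invisible by construction; the simulator only places tangential
  dipoles.
- The Hilbert phase near the boundary is contaminated by the reset
  discontinuity smeared through the 4 Hz filter (~±0.3 s); the phase-
  preservation guarantee is stated for the broadband chain, and ITPC
  effects are driven by the post-boundary window where contamination is
  common to all levels.
- The AGQ GLMM supports a single scalar random intercept — exactly what
  the models here need, not a general mixed-model engine.
- Cluster p-values are valid under exchangeability of level labels
  within participant; designs with level-dependent trial counts would
  need the bias-aware ITPC variant before the regression.
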