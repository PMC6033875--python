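# Methods

## Generative model

Each simulated observer is an equal-variance signal-detection decision maker.
On a trial with internal sensitivity δ the decision evidence is

    e ~ Normal(s · δ/2, 1),    s = +1 for "higher" targets, −1 for "lower",

and the observer responds "higher" iff e > c, where c is a per-observer
response criterion.  With probability `lapse_rate` the response is replaced
by a fair coin flip; a configurable `miss_prob` (default 0) yields omitted
responses.  Under this convention the yes/no sensitivity equals δ, and the
analysis-side 2AFC estimator d′ = [z(H) − z(F)]/√2 converges to δ/√2.

Condition sensitivities are additive on the δ scale and floored at zero:

    base_A = delta_A + max(pref_imbalance, 0)
    base_V = delta_V + max(−pref_imbalance, 0)
    high   = [spatial uncertainty high] ∨ [target uncertainty high]
    uni(m) = base_m − uncertainty_penalty_uni · high
    AV     = max(base_A, base_V) + msi_gain_base + msi_gain_uncertainty · high
             + msi_pref_slope · |base_A − base_V| + seq_tp_gain_av · [n−1 TP match]
    δ      = max(0, cell + te_gain · [temporally expected])

The additive-on-δ construction is a modelling choice: the study this design
emulates is an analysis of real behaviour and prescribes no generative
process, so the generator is the simplest observer family in which every
analysed contrast corresponds to exactly one interpretable gain parameter.
The AV base is the better unisensory base so that `msi_gain_base` *is* the
max-criterion facilitation in expectation, and the negative coupling
`msi_pref_slope · |base_A − base_V|` reproduces the finding that facilitation
shrinks as the unisensory imbalance grows.

Response times are shifted lognormal with additive mean effects,

    rt = rt_shift_ms + Lognormal(rt_mu, rt_sigma) − rt_te_effect_ms · [expected]
         − rt_av_effect_ms · [AV],   floored at 150 ms.

Defaults (shift 600 ms, μ 6.93, σ 0.3, TE effect 110 ms, AV effect 60 ms)
put cohort mean RTs near 1530 ms for expected and 1640 ms for unexpected
targets.  These are configuration defaults chosen to land in the empirically
reported range, not ground truth.

### Population defaults

`default_observer_sampler` draws, per subject (all gains in δ units):

| parameter | distribution | role |
|---|---|---|
| delta_A, delta_V | LogNormal(log 1.3, 0.25) | pre-calibration sensitivity per unit frequency offset |
| pref_imbalance | Normal(0.15, 0.55) | modality preference (slight auditory bias) |
| te_gain | Normal(0.26, 0.15), ≥ 0 | temporal-expectation gain |
| msi_gain_base | Normal(0.17, 0.12) | audiovisual gain |
| msi_gain_uncertainty | Normal(0.25, 0.12), ≥ 0 | extra AV gain under high uncertainty |
| msi_pref_slope | Normal(−0.35, 0.12), ≤ 0 | preference–facilitation coupling |
| uncertainty_penalty_uni | Normal(0.5, 0.2), ≥ 0 | unisensory penalty under high uncertainty |
| seq_tp_gain_av | Normal(0.25, 0.12), ≥ 0 | n−1 target-position repetition gain (AV) |
| criterion | Normal(0, 0.15) | response bias |
| lapse_rate | Uniform(0, 0.05) | attentional lapses |

Means follow the directions and approximate magnitudes of the reported group
effects once divided by √2 onto the d′ scale (e.g. a TE gain of 0.26
corresponds to a d′ difference of ≈0.18).  `null_observer_sampler` zeroes
every gain and is used for type-I calibration.

## Threshold calibration

The threshold stage of the emulated procedure adjusts each modality's target
frequency until accuracy reaches 75%, with balanced early/late targets and
no temporal manipulation.  `calibrate_threshold` computes the calibrated
sensitivity by root-finding (Brent bisection) on the observer's analytic
psychometric function

    acc(δ) = (1 − λ) · [Φ(δ/2 − c) + Φ(δ/2 + c)]/2 + λ/2,

i.e. the exact point an adaptive track would converge to; threshold-block
trial records are still generated in the session layout.  A finite-length
empirical staircase would carry a standard error of ~0.15–0.3 in δ over 144
trials and make the calibrated accuracy itself a random variable several
percentage points wide; solving the psychometric equation keeps the
validation accuracy exact up to binomial sampling error, which is what the
calibration checks assert.  If the accuracy level is unreachable (extreme
criterion or lapse rate) a `CalibrationError` is raised.  The calibrated
frequency offsets δ*/delta_m are carried as per-subject covariates and,
normalized by their grand means, become the FreqA/FreqV predictors.

Because calibration equalizes A and V at 75%, post-calibration modality
preference arises from `pref_imbalance` (and from TE acting on the main
blocks) — mirroring the observation that preferences emerge in the main task
despite an equalizing threshold procedure.

## Analysis chain

**Filtering.**  The analysis set keeps early-position targets in main blocks
whose RT lies in the closed window [150, 3000] ms after target onset and
(by default) carries a response.  A row failing several rules is tallied
once, precedence window > position > block > response.  The window is
treated as closed because the verbal specification ("from 150 to 3000 ms")
names no endpoint convention.  n−1 annotation always runs before filtering
and never crosses block boundaries (blocks differ in expectation context and
are separated by breaks), so the "previous trial" is the physically
preceding trial of the same block, whatever its type.

**Scoring.**  te_state is defined for early targets as expected in
expect-early and unexpected in expect-late blocks (late targets, when
included via the filter switch, are classified symmetrically).  Extreme-rate
protection uses the log-linear correction (+0.5 to each count, +1 to each
denominator) by default; 1/(2N) clamping is selectable.  Mean RT uses all
responded trials surviving the filters; a `rt_correct_only` switch restricts
to correct ones.

**Best-unisensory selection.**  Step 1 picks the modality better in both
expectation states (higher d′, or lower RT); on split dominance step 2 picks
the better unweighted mean.  An exact tie after step 2 is broken by the
larger analyzed trial count, then A, and flagged.  Selection may differ
between measures; the label (auditory/visual/mixed) feeds the PrefA/PrefV
indicators.  MSF outcomes use the subject-level selected modality; the
UniDiff predictor uses the state-wise max[A,V] − min[A,V] spread, which is
non-negative by construction.

**ANOVA.**  All within factors here have two levels, so every within effect
is one degree of freedom and reduces to a per-subject contrast score; the
mixed ANOVA decomposes into a between-subjects factorial on subject means
(error: subjects within groups) plus one factorial per within effect on the
contrast scores (error: effect × subjects within groups).  This direct SS
decomposition is auditable — with one within factor and no between factors
F equals the paired t² identically — and is cross-checked in the test suite
against independent implementations.  Sphericity corrections are moot with
two-level factors.  Generalized η² divides by the sum of all subject-level
error strata; η² is reported in its partial form (the convention of the
common point-and-click ANOVA tools).  Unbalanced group sizes are rejected
unless explicitly allowed, in which case the unweighted-means approximation
is used and flagged.  The JZS Bayes factor for paired contrasts uses the
Cauchy(√2/2) prior evaluated by quadrature; it is an approximation to the
defaults of common Bayesian t-test tools and is attached to non-significant
contrasts only.

**Model comparison.**  The three-level preference factor is coded as two
indicator columns (PrefA, PrefV; mixed = both zero) — the only coding that
yields exactly 8 predictors and hence 255 subset models.  TE is coded 1 for
temporally unexpected rows.  Every model includes an intercept, fit by OLS;
leave-one-out residuals use the exact hat-matrix identity e_i/(1 − h_ii)
(verified against naive per-fold refits to 1e-8).  Models are ranked by
LOOCV RMSE; ties break by smaller subset, then canonical bitmask order.
Spearman p-values use the t approximation with average-rank ties and are
Bonferroni-corrected over the five reported models per measure (the family
size is configurable).  PRE is computed on the full-data fit by removing one
predictor at a time with the intercept retained.

**Trial history.**  A trial enters the history analysis only if its
predecessor exists within the block and was answered correctly (no
post-error trials).  Modality match is plain equality with the current
trial's modality — an AV predecessor of a unisensory trial is a mismatch,
and AV trials match only AV predecessors; this is the strictest reading of
the match examples and is switchable in principle by reclassifying the
annotated table.  Cells are 2×2×2 per subject (modality {AV, best-uni} ×
modality match × TP match); subjects with an incomplete cell set are dropped
with a log entry.

## Numerical and degenerate-case choices

* d′ with zero targets of either direction is undefined: such cells are
  dropped (and counted) rather than imputed.
* `condition_sensitivity` floors δ at 0; `simulate_response` rejects
  negative δ.
* LOOCV raises on rank-deficient designs and on leverage-one folds rather
  than returning silently infinite predictions.
* Paired contrasts with zero-variance differences raise a degenerate-case
  error; the Bayes-factor quadrature raises if its error estimate is not
  negligible.
* All randomness flows from a single master seed: each subject's stream is
  keyed by (master seed, experiment, subject), so any cohort subset is
  reproducible in isolation, and identical seeds give byte-identical tables.

## What the generator emulates — and what it does not

Emulated: the full block structure (training, two threshold blocks, three
expect-early and three expect-late blocks in alternation with the starting
type counterbalanced by subject parity), per-block modality counts and
50/50 direction balance, Bernoulli target-position assignment at the
block-type probabilities (0.86/0.43 — the printed percentages are
non-integer multiples of the per-modality trial count, so exact quotas are
not enforced and long-run proportions match instead), sequence timing
(11 events × 100 ms + 100 ms gaps; early onset 400 ms, late 1600 ms), the
uncertainty factors across the four experiments, and observer-level TE/MSI/
preference/sequential effects.

Not emulated: actual stimulus rendering and hardware timing, eye movements,
fatigue or learning within a session, RT–accuracy coupling (RTs are
condition-shifted noise, not evidence-accumulation times), omitted responses
(default rate 0), and any trial-to-trial drift of the criterion.  Passing
tests therefore demonstrate that the analysis chain recovers effects of the
assumed additive-Gaussian observer family — not that real data obey that
family.

A difference worth noting: the default population yields more
mixed-preference observers (~55%) than typically reported for real cohorts
(~23%), because measurement noise in the two selection measures is
independent in the generator; the preference indicators still carry the
intended signal.

## Known statistical caveat of the max-criterion

best[A,V] is the maximum of two noisy d′ estimates and is therefore
upward-biased under the null: with all generative gains at zero, AV −
best[A,V] is biased negative, and the ANOVA modality main effect rejects far
above the nominal rate (~20% in 200 null cohorts of 8 subjects).  This is a
property of the max-criterion itself, not of the implementation — the
exchangeable effects (TE, the uncertainty factors, their interactions with
TE, and the history modality × TP-match interaction) all reject at the
nominal 5% under the same nulls.  Interpreting a raw modality main effect
as facilitation requires this bias in mind; the regression stage's negative
coupling between measured UniDiff and MSF contains a related shared-noise
component (the same max enters both with opposite sign).

## Problem sizes used by the test suite

Structural and proportion checks run on one full-size cohort (120 subjects).
Calibration validation uses 10,000-trial blocks.  Directional recovery uses
100 cohorts of 4 × 8 subjects at full session length; type-I calibration
uses 200 null cohorts of 4 × 2 subjects at full session length (full-length
sessions keep the small-sample correction bias across unequal TE cell
counts negligible).  These sizes are the package's chosen study conditions
for its own validation and are large enough that the binomial 99% bands
used in the tests are informative.
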