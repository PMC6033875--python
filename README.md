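# msite

Simulation and analysis of **m**ulti**s**ensory **i**nterplay and **t**emporal
**e**xpectation in 2AFC target discrimination.

## The problem

In many psychophysical paradigms observers judge a property of a single
target (here: whether its frequency is *higher* or *lower* than surrounding
distractors) embedded in an 11-event audio/visual stream.  Two mechanisms are
known to sharpen such judgements: **temporal expectation (TE)** — block-wise
manipulation of when the target is likely to occur (early targets are
frequent in "expect early" blocks, 86%, and infrequent in "expect late"
blocks, 43%) — and **multisensory interplay (MSI)** — the benefit of
redundant audiovisual (AV) stimulation over auditory (A) or visual (V)
stimulation alone.  Whether these mechanisms interact, on which time scale,
and under which levels of spatial and target-modality uncertainty, is the
question this pipeline addresses.

The package is aimed at researchers who want a fully testable, reusable
implementation of that analysis chain, driven by a synthetic-data generator
that reproduces the experimental design (4 experiments × 30 subjects × 1008
main trials), so every stage can be validated against known ground truth
without access to the original data.

## What it computes

* **2AFC sensitivity** per subject × modality × expectation cell:
  d′ = [z(H) − z(F)] / √2, with H the "higher"-response rate to
  higher-frequency targets and F the corresponding false-alarm rate
  (log-linear correction by default), plus mean response times.
* **Max-criterion multisensory facilitation (MSF)**: the best unisensory
  modality per subject is chosen by a two-step rule (dominance in both
  expectation states, else best average); MSF is
  d′(AV) − d′(best[A,V]) and RT(best[A,V]) − RT(AV), so positive always
  means facilitation.
* **Mixed repeated-measures ANOVA** (modality × TE within; spatial and
  target uncertainty between) with generalized η² and partial η², Bonferroni
  post-hocs, and JZS Bayes factors for non-significant paired contrasts.
* **Exhaustive-subset model comparison**: all 2⁸ − 1 = 255 OLS models over
  {SpU, TaU, TE, FreqA, FreqV, PrefA, PrefV, UniDiff} are ranked by
  leave-one-out cross-validated RMSE; Spearman ρ between held-out
  predictions and observations, coefficients, and per-predictor
  Proportionate Reduction of Error, PRE = (SSE₋ − SSE₊)/SSE₋.
* **Trial-history (n−1) analysis**: d′ conditioned on whether the previous
  (correctly answered) trial matched the current one in modality and in
  target position, for AV vs. best-unisensory targets.

The generator is a first-class module: an equal-variance signal-detection
observer whose condition sensitivities are additive gains on the internal
evidence scale (TE gain, AV gain, uncertainty penalty, preference imbalance,
n−1 repetition gain), calibrated to 75% accuracy per modality by a simulated
threshold stage, with shifted-lognormal response times.

## Worked example

```python
import msite

trials, truth = msite.generate_cohort(msite.DesignConfig(), master_seed=20240501)
filtered, tally = msite.apply_filters(msite.annotate_previous_trial(trials))
scores = msite.score_conditions(filtered)
print(scores.groupby("te_state").dprime.mean().round(3).to_dict())
# {'expected': 1.287, 'unexpected': 1.043}

cells = msite.build_modality_te_cells(scores)
anova = msite.mixed_anova(cells, dv="dprime", within=["modality", "te_state"],
                          between=["spatial_uncertainty", "target_uncertainty"])
print(anova.set_index("effect").loc["modality*te_state", ["F", "p", "ges"]].round(4).to_dict())
# {'F': 8.4421, 'p': 0.0044, 'ges': 0.0095}
```

Temporally expected targets are discriminated better (d′ 1.287 vs. 1.043),
and the TE benefit is larger for audiovisual than for best-unisensory
targets (the modality × TE interaction) — the generator injects exactly this
structure, and the analysis chain recovers it.  Continuing with the model
comparison:

```python
sel = msite.select_all_subjects(scores)
msf = msite.build_msf_records(scores, frequencies=truth[["subject_id", "freq_a", "freq_v"]],
                              selections=sel)
matrix = msite.build_predictor_matrix(msf, "dprime")   # 240 rows x 8 predictors
results, named = msite.rank_models(matrix)             # 255 LOOCV-ranked models
print({k: (int(v['rank']), round(v['rmse'], 3), round(v['rho'], 3)) for k, v in named.items()})
# {'best': (1, 0.369, 0.511), 'physical': (95, 0.395, 0.389),
#  'individual': (254, 0.432, -0.41), 'uni_perf': (150, 0.409, 0.275),
#  'full': (13, 0.372, 0.5)}
```

The best model's unisensory-difference coefficient is negative
(β = −0.48): the more a simulated observer favours one modality, the less
multisensory facilitation it shows, matching the generator's negative
preference–MSI coupling.

The same analyses are scriptable from the shell:

```bash
msite run --config pipeline.yml --seed 7 --out results/
```

which chains simulate → filter → score → anova → modelsel → history and
writes a manifest with file digests for byte-identical reproduction.

## Layout

| module | contents |
|---|---|
| `msite.simulate` | design config, SDT observer, calibration, cohort generator |
| `msite.trial_io` | table I/O, response-window/position filters, n−1 annotation |
| `msite.sdt` | 2AFC d′, condition scores, best-unisensory selection, MSF records |
| `msite.anova` | mixed ANOVA by direct SS decomposition, post-hocs, JZS Bayes factors |
| `msite.modelsel` | subset enumeration, LOOCV, ranking, coefficients, PRE |
| `msite.history` | n−1 match classification and history d′ cells |
| `msite.cli` | `msite` command with per-stage subcommands and `run` |

See `docs/methods.md` for the generative model, parameter defaults, numerical
choices and known limitations.
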