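# lfpdecode

Decoding feeding behavior from ventral-striatal local field potentials.

`lfpdecode` is a tested re-implementation of a neural-decoding pipeline
for rat limited-access ("binge") feeding studies: four LFP channels in
the nucleus accumbens core and shell (SL, SR, CL, CR) are reduced to
per-5-second-bin **band power** (4 channels × 6 bands) and
**magnitude-squared coherence** (6 pairs × 6 bands) features — 60 in
total, 58 after artifact exclusions — in the canonical bands delta
(1–4 Hz), theta (5–10), alpha (11–14), beta (15–20), low gamma (45–65)
and high gamma (70–90 Hz). On top of those features it answers:

* **Whole-session** — predict grams/kcal consumed, deprivation-induced
  change, and food type from rest-normalized session vectors
  (feeding-bin mean − rest-bin mean per feature), using the lasso with
  100 iterations of 5-fold cross-validation, Monte-Carlo chance
  references, and Mann-Whitney-U–derived Cohen's *d* effect sizes.
* **Within-session** — classify bins as feeding / imminent-feeding
  (pre-feeding, up to 42.5 s before onset) vs not-feeding with
  ADASYN-balanced logistic models, repeated 80/20 evaluation with
  permuted twins, leave-one-animal-out and individualized designs,
  cross-condition generalization, and learning curves.
* **Model complexity** — exhaustively score all 58 monads, 1,653 dyads
  and 30,856 triads against lasso and full-logistic references on
  shared test sets, extract the statistically indistinguishable "top
  tier", per-band frequency contributions, lasso survival frequencies,
  and the minimal model class matching the full 58-feature logistic.
* **Peri-event dynamics** — onset/offset-aligned feature traces
  exposing the pre-feeding ramp and the during-feeding variance
  collapse.

Because such recordings are rarely shareable, the package includes a
first-class synthetic cohort generator (`lfpdecode.synth`) that plants
known effects — state-dependent mean shifts, a 45-s pre-onset ramp,
feeding-state variance shrink, between-animal and between-condition
random effects, and session-level intake outcomes — either as raw
multichannel signals (band-limited carrier synthesis) or directly as
feature tables. Every analysis stage is validated by recovering what
the generator planted.

## Worked example

Run the study-shaped synthetic experiment (12 animals × 4 conditions,
planted alpha/high-gamma feeding effects; ~2 minutes on one CPU):

```bash
lfpdecode run --preset paper-synthetic --out run/ --seed 7
```

Selected output (`run/results.json`, plus tidy CSVs per stage):

```
population_feeding:  AUC 0.92 [0.92, 0.93], permuted 0.56, d = 3.16
prefeeding:          AUC 0.76 [0.67, 0.88], permuted 0.51, d = 2.62
variance_ratio_SLhg: 0.64 (Levene p < 1e-70)
```

The population feeding-vs-not-feeding classifier is far from its
permuted twin (*d* ≈ 3); pre-feeding bins immediately before onset are
separable from not-feeding at AUC 0.76 while the matched permuted
pipeline sits at chance; and the planted feeding-state variance shrink
on shell-left high-gamma power is recovered as an SD ratio well below
1. The backtest (`run/prefeeding_backtest.csv`) shows the ramp
geometry — AUC declines from 0.76 at lag 2.5 s to chance at 42.5 s —
and the monad sweep (`run/sweep_k1.csv`) finds the planted core
left/right high-gamma coherence as the best single feature
(AUC 0.78, sole member of the monad top tier, so the band
contribution table reads 100% high gamma).

The same machinery runs on real data: read a recording
(`.npy` + JSON sidecar, CSV matrix, or EDF), extract features, and
label bins from a scored interval CSV:

```bash
lfpdecode extract-features --in session.edf --behavior intervals.csv --out features.csv
```

or from Python:

```python
from lfpdecode import STUDY_SPEC, build_feature_table, label_bins, BehaviorIntervals
from lfpdecode.io import read_recording

rec = read_recording("session.edf")
table = build_feature_table(rec, STUDY_SPEC)            # bins x 58 features
iv = BehaviorIntervals.from_csv("intervals.csv", rec.duration_s)
table = label_bins(table, iv)                           # + label/rest/lag columns
```

## Layout

```
src/lfpdecode/
  bands.py           channel layout, band definitions, feature naming
  synth.py           synthetic cohort generator (signals or features)
  features.py        binning, Welch band power, band coherence
  labeling.py        feeding / pre-feeding / not-feeding (+rest) labels
  whole_session.py   rest normalization, lasso CV, permutation nulls, U->d
  within_session.py  ADASYN, classifiers, repeated eval, generalization
  sweep.py           monad/dyad/triad sweeps, top tier, minimal model
  perievent.py       onset/offset-aligned traces, variance collapse
  pipeline.py        one-command orchestration, presets, manifests
  cli.py, plots.py, io.py
```

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and what the synthetic generator does and does not emulate.
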