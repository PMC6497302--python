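# Methods

## The problem

In a rat limited-access ("binge") feeding paradigm, local field
potentials (LFPs) are recorded from four single-wire electrodes in the
ventral striatum — nucleus accumbens shell left/right (SL, SR) and core
left/right (CL, CR) — while video is scored for feeding, approach, and
rest. Two families of questions are asked of these data:

* **Whole-session** — can a session's average neural state predict
  session outcomes (grams/kcal consumed, the deprivation-induced change
  in intake, the type of food eaten)?
* **Within-session** — can individual 5-second epochs be classified as
  feeding, imminent feeding (pre-feeding), or neither, and how do model
  complexity choices (number of features, number of animals, number of
  conditions in the training set) trade off against performance and
  generalization?

No recordings ship with this package. A synthetic cohort generator
produces signals and behavior with the statistical structure the
analysis assumes, so every stage is testable end to end.

## Feature extraction

Recordings are cut into non-overlapping 5-s bins. Within each bin,
Welch's method (1-s Hann segments, 50% overlap, constant detrend; K = 9
segments per bin, 1-Hz grid) estimates the PSD per channel and the
magnitude-squared coherence (MSC) per channel pair. Six canonical
bands summarize each spectrum: delta 1–4, theta 5–10, alpha 11–14,
beta 15–20, low gamma 45–65, high gamma 70–90 Hz. Band power is the
trapezoid integral of the PSD over the band; band coherence is the mean
MSC across band frequencies. The 20–45 Hz gap is deliberately
unanalyzed. The full grid is 4×6 power + 6×6 coherence = 60 features;
two coherence features (`SLCLt`, `SLCRt`, the chewing-artifact screen's
prime suspects on the shell-left wire) are excluded by default, leaving
the 58 used for modeling. Exclusions are configuration, not code.

Numerical choices: bins with NaN samples or a zero-variance channel are
dropped, never imputed; coherence of a zero-variance channel is an
error, not a silent zero; band edges are inclusive on the Welch grid.
Note the MSC estimator is biased upward for independent signals by
roughly 1/K_eff (~0.13 here); tests compare against a brute-force FFT
oracle rather than assuming zero.

## Behavior labeling

Every bin receives exactly one label. A bin touching any scored
feeding interval is `feeding` (the conservative any-overlap rule, which
avoids leaking feeding activity into the negative class). Otherwise a
bin whose center lies within 45 s before a feeding onset — and which
does not overlap an earlier feeding epoch — is `prefeed`, with a lag
recorded on the 9-position grid 2.5, 7.5, …, 42.5 s (bin-center seconds
before onset; continuous onsets are snapped to the grid by the
containing-bin rule). Everything else is `notfeed`; not-feeding bins
overlapping scored rest intervals carry an additional `rest` flag
(rest is a sub-category of not-feeding, and rest-flagged bins sit on
the negative side of classifiers).

## Whole-session models

Per session, each feature is averaged over feeding bins and over rest
bins; the predictor is feeding mean − rest mean ("rest
normalization", cancelling day-to-day drift; the sign convention is
configurable). Deprivation contrasts use Base − deprived differences
of these vectors within animal.

Outcomes are fit with the lasso under repeated 5-fold cross-validation
(100 iterations by default). Continuous outcomes: coordinate-descent
lasso over a 30-point geometric penalty grid; the penalty minimizing
pooled out-of-fold MSE is selected and out-of-fold MAE reported per
iteration. Binary outcomes: L1-penalized logistic regression, with
the penalty chosen by *nested* inner cross-validation (3 folds, log-loss)
inside each training fold, so the reported out-of-fold accuracy carries
no selection-on-test bias; accuracy uses a 0.5 probability threshold.
Per-feature selection frequency ("survival") across iterations comes
from a full-data refit at the chosen penalty.

The binary CV loop is powered by a batched proximal-gradient (FISTA)
L1-logistic path solver (`whole_session.l1_logistic_path`, intercept
unpenalized) that fits all penalty values — and, in the Monte-Carlo
null, all outcome draws — in shared matrix products. It is verified
against scikit-learn's liblinear solver in the test suite.

**Chance reference.** The Monte-Carlo null re-runs the full CV
procedure on chance outcomes and pools the per-iteration metrics.
For continuous outcomes the null shuffles y. For binary outcomes the
null *resamples* the outcome i.i.d. at the observed class rate rather
than exchanging labels: with ~21 sessions and fixed class counts, label
exchange makes every training fold's majority anti-predict its test
fold, pushing CV accuracy far below 50% as an artifact of the fixed
count, not of the data; the resampling null centers at the class
agreement rate (~50% for near-balanced classes) and is the reference
that a 50% "by chance" claim actually describes. Performance vs null
is summarized by a Mann-Whitney U test converted to Cohen's d
(U → z with tie correction, r = z/√N, d = 2r/√(1−r²)); the conversion
lives in one function so it can be swapped.

**Chewing-artifact screen.** Feeding introduces jaw-muscle artifact
candidates. For each feature, the percent change (Base → deprived,
within animal) of the rest-normalized value is regressed on the percent
change in voracity (kcal per minute of feeding); features with p < 0.01
are flagged as exclusion candidates. The screen is skipped (with a
warning) below 5 paired observations or under constant voracity.

## Within-session models

Classifiers are logistic regressions (optionally L1-penalized) on bin
feature vectors. Feeding is rare (~18% of bins), so training data are
balanced with ADASYN (k = 5, β = 1, synthetic points interpolated toward
minority neighbors, generation counts proportional to the majority
fraction of each minority point's neighborhood). Balancing is applied
to training data only; synthetic points never reach a test set.
Evaluation is repeated stratified 80/20 splitting (within animal and
class; within lag for pre-feeding tasks), 20 iterations by default,
scored as ROC AUC on the naive held-out set, with a permuted twin
(training labels shuffled before balancing) matched split-for-split.
Label permutation is the appropriate null here — AUC has no
majority-class artifact — and calibrates to ~0.51–0.53 on this
generator, slightly above 0.5 because ADASYN's density weighting
interacts with the variance structure of the feeding state.

Generalization designs: population (all animals pooled), leave-k-
animals-out, individual (one animal's own split), all-subsets
animal-count sweeps (capped with a seeded subsample beyond 30 subsets
per k), Base-only vs all-condition training with equalized bins per
condition, pre-feeding backtests (train at lag 2.5 s, test each lag),
and bins-per-animal learning curves with a Bonferroni-corrected plateau
test.

## Complexity sweep

All C(58,1) = 58 monads, C(58,2) = 1,653 dyads, and C(58,3) = 30,856
triads are scored with the same per-iteration splits and the same
balanced training sets as the lasso and full-logistic references
(balance once on the full feature space, then select columns), so
families are directly comparable. "Top tier" = subsets not
significantly worse than the best subset (Welch two-sample t,
Bonferroni over the subsets-minus-one comparisons within each k
group). Frequency contribution = percent of top-tier models containing
at least one feature of each band (rows need not sum to 100 for k > 1).
The minimal-model search walks monad → dyad → triad → lasso and
returns the first class whose best member is not significantly worse
than the full 58-feature logistic. For triad-scale sweeps a two-pass
screening mode (few iterations for all subsets, full evaluation of the
top fraction) is available; exact single-pass evaluation is default.

## Peri-event analysis

Feeding epochs of at least 45 s (the minimum that keeps onset- and
offset-aligned windows disjoint within an epoch) are aligned at onset
(−62.5 … +32.5 s, 19 bins) and offset (−12.5 … +52.5 s, 13 bins);
outside-feeding bins overlapping any other epoch are masked. Traces
report per-aligned-bin mean ± across-epoch SD (display-normalized by
per-bin total power or mean pair coherence). Variance collapse is
quantified as the SD ratio feeding/non-feeding over the aligned bins
with a Levene test.

## The synthetic cohort generator

Defaults mirror the emulated study design: 12 animals × four
conditions (Base with two recordings per animal, 24-h and 48-h food
deprivation, chow-after-deprivation), 2-h sessions at 1 kHz, ~18% of
bins feeding. Feeding epochs have lognormal durations (median ≈ 67 s)
placed by condition-specific mixtures over normalized session time —
Base bimodal (early and late mode), deprived and chow conditions
front-loaded — with the last epoch trimmed to hit the feeding-time
target. Approach intervals (10 s) precede 30% of onsets; rest fills
the interior of long quiescent gaps to ~30% of the session. Intake
outcomes follow a linear model on the session's realized feature
shifts plus Gaussian noise (sweet-fat food at 4.6 kcal/g, chow at
3.1 kcal/g), giving the whole-session lasso a recoverable target; an
optional chew-confound couples one feature's shift to voracity for
testing the artifact screen.

Planted structure, shared by both output levels:

* `effect_table` — standardized mean shift of each named feature during
  feeding (defaults put the signal in alpha and high gamma: SLhg −1.0,
  CLCRhg +1.0, SLa/SRa +0.8, CRhg +0.6, SLCRhg +0.5);
* a linear ramp of those shifts over the 45 s before onset (the paper-
  shaped "ramping" geometry; ramps are otherwise unparameterized, so
  linear is the package's choice);
* `variance_shrink` — multiplicative factor (default 0.6) on the
  per-bin SD of the planted-effect features during feeding. The shrink
  is deliberately scoped to the informative features: the
  variance-collapse phenomenon rides particular features, and shrinking
  the whole grid would make the feeding state a uniformly dense cluster
  that ADASYN amplifies even under label permutation;
* Gaussian between-animal (`animal_sd`, default 0.3) and
  between-condition (`condition_sd`, default 0.15) random effects on
  the planted shifts, plus fixed condition-specific shift tables —
  these drive the individual-vs-population and cross-condition
  phenomena.

**Signal level** (`generate_cohort`): each channel is a sum of six
band-limited filtered-noise carriers; per-bin log2 amplitude realizes
the power effects, and per-bin mixing between a band-shared carrier and
private noise realizes pair coherence (baseline shared fraction 0.3;
coherence effects modulate the two channels of the target pair on the
logit scale, with small cross-talk onto pairs sharing a channel).
**Feature level** (`generate_feature_cohort`): unit-variance Gaussian
features with the same schedule and effect machinery, for
classifier-scale experiments at a fraction of the cost.

What the generator does *not* emulate: 1/f background spectra, mains
noise, movement and chewing artifacts in the raw signal, non-Gaussian
feature distributions, temporal autocorrelation of features beyond the
behavioral state, electrode-placement physics. Passing tests therefore
demonstrate that the *analysis machinery* recovers planted structure
under the stated statistical assumptions — not that real recordings
contain such structure.

## Problem sizes

The generator's distributional defaults are the study conditions; the
test suite and the acceptance script choose smaller *problem sizes* —
typically 900–1800-s sessions at 250–500 Hz, 3–12 animals, reduced
iteration counts — which leave every rate, effect size, and proportion
untouched. Sampling at 250 Hz keeps all bands below Nyquist with the
same 1-Hz Welch grid.

## Known limitations

* The original study's exact PSD estimator, filtering, ADASYN settings,
  CI construction, and U→d formula live in unavailable supplementary
  code; the choices above are standard, documented stand-ins, isolated
  so they can be swapped.
* Which two features the study excluded to reach 58 is unstated; the
  default exclusion pair is this package's choice.
* MSC-based coherence control in the signal generator is approximate
  (per-channel shared fractions couple pairs that share a channel);
  exact per-pair coherence control would need per-pair carriers.
* Session files are written as float32 `.npy` matrices with JSON
  sidecars (plus interval CSV and metadata JSON); EDF is supported for
  reading (via `mne`) but not writing.
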