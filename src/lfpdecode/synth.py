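"""Synthetic cohort generator.

Emulates a limited-access ("binge") feeding study: a cohort of animals,
each recorded across hunger/palatability conditions (Base, Dep24,
Dep48, Chow) for ~2-hour sessions, with scored feeding / approach /
rest intervals and 4-channel LFP whose band power and coherence shift
with behavioral state.  The generator plants:

* a per-feature standardized mean shift during feeding (``effect_table``),
* a linear ramp of those shifts over the seconds before feeding onset,
* a multiplicative shrink of per-bin feature SD during feeding,
* Gaussian between-animal and between-condition random effects on the
  planted shifts, and
* session-level intake outcomes (grams/kcal) drawn from a linear model
  on the session's realized feature shifts.

Two output levels share the same schedule and effect machinery:
``generate_cohort`` synthesizes continuous signals (band-limited
filtered-noise carriers whose per-bin envelopes and cross-channel
mixing set power and coherence), while ``generate_feature_cohort``
emits per-bin feature tables directly — the cheap path for
classifier-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import DEFAULT_BANDS, FeatureSpec
from .features import SessionRecording
from .labeling import BehaviorIntervals, LabelConfig, label_bins

__all__ = [
    "CohortConfig",
    "SessionMeta",
    "SyntheticSession",
    "ConfigError",
    "GenerationError",
    "generate_behavior_schedule",
    "generate_cohort",
    "generate_feature_cohort",
    "cohort_table",
    "DEFAULT_EFFECTS",
]


class ConfigError(ValueError):
    """Invalid generator configuration (message names the field)."""


class GenerationError(RuntimeError):
    """Schedule constraints could not be satisfied."""


KCAL_PER_GRAM = {"sweet_fat": 4.6, "chow": 3.1}

# Study-shaped planted feeding effects (standardized shift of the
# per-bin feature during feeding vs not-feeding).  Alpha and high gamma
# carry the signal; shell-left high-gamma power drops while core
# left/right high-gamma coherence rises during feeding.
DEFAULT_EFFECTS: dict[str, float] = {
    "SLhg": -1.0,
    "CLCRhg": 1.0,
    "SLa": 0.8,
    "SRa": 0.8,
    "CRhg": 0.6,
    "SLCRhg": 0.5,
}

# Condition-specific modifications of the feeding effect (added to
# effect_table entries for sessions of that condition).
DEFAULT_CONDITION_EFFECTS: dict[str, dict[str, float]] = {
    "Chow": {"SLa": -0.8, "CLCRhg": -0.6, "SRhg": 0.5},
    "Dep48": {"SLhg": -0.4, "SRa": 0.4},
}

# Session-level intake model: grams = base(condition) + sum w_f * realized
# feeding shift + noise.
DEFAULT_KCAL_WEIGHTS: dict[str, float] = {"SLa": 1.5, "CLCRhg": -1.0}
CONDITION_BASE_GRAMS = {"Base": 10.0, "Dep24": 11.5, "Dep48": 13.0, "Chow": 12.0}

# Normalized-time mixtures for feeding-epoch placement: (weights,
# means, sds).  Base is bimodal (early + late mode); deprived and chow
# sessions front-load feeding.
_TIME_MIXTURES = {
    "Base": ([0.6, 0.4], [0.12, 0.72], [0.10, 0.12]),
    "Dep24": ([0.85, 0.15], [0.08, 0.55], [0.07, 0.25]),
    "Dep48": ([0.9, 0.1], [0.07, 0.55], [0.06, 0.25]),
    "Chow": ([0.8, 0.2], [0.10, 0.55], [0.08, 0.25]),
}
_DEFAULT_MIXTURE = ([0.7, 0.3], [0.15, 0.6], [0.1, 0.2])


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 12 animals, four conditions
    with two Base recordings per animal, 2-hour sessions at 1 kHz, and
    ~18% of 5-s bins spent feeding.
    """

    n_animals: int = 12
    conditions: tuple[str, ...] = ("Base", "Dep24", "Dep48", "Chow")
    n_base_sessions: int = 2
    session_length_s: float = 7200.0
    sampling_rate_hz: float = 1000.0
    bin_length_s: float = 5.0
    feeding_fraction: float = 0.18
    effect_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    condition_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_EFFECTS.items()}
    )
    ramp_length_s: float = 45.0
    variance_shrink: float = 0.6
    # features whose per-bin SD shrinks during feeding; None -> the
    # planted-effect features (variance collapse rides the informative
    # features, not the whole grid)
    variance_shrink_features: tuple[str, ...] | None = None
    animal_sd: float = 0.3
    condition_sd: float = 0.15
    approach_prob: float = 0.3
    approach_duration_s: float = 10.0
    rest_fraction: float = 0.3
    epoch_log_mean: float = 4.2
    epoch_log_sd: float = 0.5
    min_epoch_s: float = 15.0
    max_epoch_s: float = 300.0
    min_gap_s: float = 20.0
    kcal_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KCAL_WEIGHTS))
    grams_noise_sd: float = 1.0
    chew_confound_feature: str | None = None
    chew_confound_gain: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if not 0 <= self.feeding_fraction < 1:
            raise ConfigError("feeding_fraction must be in [0, 1)")
        n = self.session_length_s / self.bin_length_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("session_length_s must be divisible by bin_length_s")
        if self.sampling_rate_hz <= 2 * max(b.hi_hz for b in DEFAULT_BANDS):
            raise ConfigError("sampling_rate_hz too low for the analysis bands")
        if self.variance_shrink <= 0:
            raise ConfigError("variance_shrink must be positive")
        if self.ramp_length_s < 0:
            raise ConfigError("ramp_length_s must be >= 0")
        if not 0 <= self.rest_fraction < 1:
            raise ConfigError("rest_fraction must be in [0, 1)")


@dataclass
class SessionMeta:
    animal_id: str
    condition: str
    session_id: str
    food_type: str
    grams_consumed: float
    kcal_consumed: float
    kcal_per_gram: float
    session_length_s: float

    def __post_init__(self) -> None:
        if self.condition == "Chow" and self.food_type != "chow":
            raise ValueError("Chow condition implies chow food type")
        if abs(self.kcal_consumed - self.grams_consumed * self.kcal_per_gram) > 0.51:
            raise ValueError("kcal_consumed inconsistent with grams * kcal_per_gram")


@dataclass
class SyntheticSession:
    meta: SessionMeta
    intervals: BehaviorIntervals
    recording: SessionRecording | None = None
    features: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# behavior schedule
# ---------------------------------------------------------------------------

def _mixture_times(condition: str, n: int, rng: np.random.Generator) -> np.ndarray:
    w, mu, sd = _TIME_MIXTURES.get(condition, _DEFAULT_MIXTURE)
    comp = rng.choice(len(w), size=n, p=np.asarray(w) / np.sum(w))
    return rng.normal(np.asarray(mu)[comp], np.asarray(sd)[comp])


def generate_behavior_schedule(
    config: CohortConfig, condition: str, rng: np.random.Generator
) -> BehaviorIntervals:
    """Draw one session's feeding/approach/rest intervals.

    Feeding onsets are sampled from a condition-specific mixture over
    normalized session time (Base bimodal with a second late mode;
    deprived conditions front-loaded); epoch lengths are lognormal and
    the last epoch is trimmed so total feeding time matches the
    configured fraction.  Approach intervals precede a random subset of
    feeding onsets; rest fills the interior of long quiescent gaps.
    """
    config.validate()
    L = config.session_length_s
    target = config.feeding_fraction * L
    rows: list[tuple[float, float, str]] = []
    epochs: list[tuple[float, float]] = []

    if target > 0:
        total = 0.0
        attempts = 0
        while total < target:
            attempts += 1
            if attempts > 5000:
                raise GenerationError(
                    "could not reach requested feeding_fraction with the "
                    "configured epoch-length distribution and gaps"
                )
            dur = float(
                np.clip(
                    rng.lognormal(config.epoch_log_mean, config.epoch_log_sd),
                    config.min_epoch_s,
                    config.max_epoch_s,
                )
            )
            dur = min(dur, target - total + config.min_epoch_s)
            start = float(_mixture_times(condition, 1, rng)[0]) * L
            if start < 0 or start + dur > L:
                continue
            if any(
                start < e + config.min_gap_s and s - config.min_gap_s < start + dur
                for s, e in epochs
            ):
                continue
            if total + dur > target:  # trim the last epoch to hit the target
                dur = max(target - total, min(config.min_epoch_s, dur))
            epochs.append((start, start + dur))
            total += dur
        epochs.sort()
        rows += [(s, e, "feeding") for s, e in epochs]

        for s, e in epochs:
            if rng.random() < config.approach_prob:
                a0 = max(0.0, s - config.approach_duration_s)
                if not any(a0 < fe and fs < s for fs, fe in epochs if (fs, fe) != (s, e)):
                    rows.append((a0, s, "approach"))

    # rest: central part of gaps >= 60 s, until rest_fraction is covered
    bounds = [0.0] + [t for se in epochs for t in se] + [L]
    gaps = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
    rest_target = config.rest_fraction * L
    rest_total = 0.0
    margin = 15.0
    order = rng.permutation(len(gaps))
    for gi in order:
        g0, g1 = gaps[gi]
        if g1 - g0 < 60.0 or rest_total >= rest_target:
            continue
        r0, r1 = g0 + margin, g1 - margin
        dur = min(r1 - r0, rest_target - rest_total)
        if dur < 10.0:
            continue
        rows.append((r0, r0 + dur, "rest"))
        rest_total += dur

    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    return BehaviorIntervals(df, session_length_s=L)


# ---------------------------------------------------------------------------
# planted per-bin effect machinery (shared by both output levels)
# ---------------------------------------------------------------------------

def _state_weights(
    intervals: BehaviorIntervals, n_bins: int, bin_length: float, ramp_length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin effect weight in [0,1] and a feeding mask.

    Weight is 1 for bins overlapping feeding; for other bins whose
    center lies within ``ramp_length`` before some onset, the planted
    shift ramps linearly from 0 to 1 toward the onset; else 0.
    """
    starts = np.arange(n_bins) * bin_length
    centers = starts + bin_length / 2
    feed = intervals.of("feeding")
    fs, fe = feed.start_s.to_numpy(), feed.end_s.to_numpy()
    w = np.zeros(n_bins)
    feeding = np.zeros(n_bins, dtype=bool)
    for i in range(n_bins):
        if len(fs) and ((fs < starts[i] + bin_length) & (fe > starts[i])).any():
            w[i] = 1.0
            feeding[i] = True
        elif ramp_length > 0 and len(fs):
            ahead = fs[fs > centers[i]]
            if len(ahead):
                lag = ahead.min() - centers[i]
                if lag < ramp_length:
                    w[i] = 1.0 - lag / ramp_length
    return w, feeding


def _session_effects(
    config: CohortConfig,
    condition: str,
    animal_effects: dict[str, float],
    condition_effects: dict[str, float],
) -> dict[str, float]:
    feats = (
        set(config.effect_table)
        | set(config.condition_effects.get(condition, {}))
        | set(animal_effects)
        | set(condition_effects)
    )
    return {
        f: config.effect_table.get(f, 0.0)
        + config.condition_effects.get(condition, {}).get(f, 0.0)
        + animal_effects.get(f, 0.0)
        + condition_effects.get(f, 0.0)
        for f in feats
    }


def _draw_random_effects(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, dict[str, float]], dict[str, dict[str, float]]]:
    feats = sorted(set(config.effect_table) | {f for d in config.condition_effects.values() for f in d})
    animal = {
        f"rat{a:02d}": {f: float(rng.normal(0, config.animal_sd)) for f in feats}
        for a in range(1, config.n_animals + 1)
    }
    cond = {
        c: {f: float(rng.normal(0, config.condition_sd)) for f in feats}
        for c in config.conditions
    }
    return animal, cond


def _make_meta(
    config: CohortConfig,
    animal_id: str,
    condition: str,
    session_id: str,
    effects: dict[str, float],
    rng: np.random.Generator,
) -> SessionMeta:
    food_type = "chow" if condition == "Chow" else "sweet_fat"
    grams = CONDITION_BASE_GRAMS.get(condition, 10.0)
    grams += sum(w * effects.get(f, 0.0) for f, w in config.kcal_weights.items())
    grams += float(rng.normal(0, config.grams_noise_sd))
    grams = max(1.0, round(grams, 1))
    kcal = round(grams * KCAL_PER_GRAM[food_type], 1)
    return SessionMeta(
        animal_id=animal_id,
        condition=condition,
        session_id=session_id,
        food_type=food_type,
        grams_consumed=grams,
        kcal_consumed=kcal,
        kcal_per_gram=KCAL_PER_GRAM[food_type],
        session_length_s=config.session_length_s,
    )


def _session_plan(config: CohortConfig) -> list[tuple[str, str, str]]:
    """(animal_id, condition, session_id) for the whole cohort."""
    plan = []
    for a in range(1, config.n_animals + 1):
        aid = f"rat{a:02d}"
        for cond in config.conditions:
            reps = config.n_base_sessions if cond == "Base" else 1
            for r in range(1, reps + 1):
                sid = f"{aid}_{cond}" + (f"_{r}" if reps > 1 else "")
                plan.append((aid, cond, sid))
    return plan


def _apply_chew_confound(
    config: CohortConfig, effects: dict[str, float], meta: SessionMeta, intervals: BehaviorIntervals
) -> dict[str, float]:
    if config.chew_confound_feature is None:
        return effects
    feed_min = (intervals.of("feeding").pipe(lambda d: (d.end_s - d.start_s).sum())) / 60.0
    voracity = meta.kcal_consumed / feed_min if feed_min > 0 else 0.0
    out = dict(effects)
    # couple the feature's feeding shift to consumption rate (chewing
    # artifact stand-in); 2.0 kcal/min is a typical session's rate
    out[config.chew_confound_feature] = (
        out.get(config.chew_confound_feature, 0.0)
        + config.chew_confound_gain * (voracity - 2.0)
    )
    return out


def _shrink_features(config: CohortConfig) -> frozenset[str]:
    if config.variance_shrink_features is not None:
        return frozenset(config.variance_shrink_features)
    feats = set(config.effect_table)
    if config.chew_confound_feature:
        feats.add(config.chew_confound_feature)
    return frozenset(feats)


# ---------------------------------------------------------------------------
# feature-level generation
# ---------------------------------------------------------------------------

def _feature_bins(
    config: CohortConfig,
    spec: FeatureSpec,
    intervals: BehaviorIntervals,
    effects: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_bins = int(round(config.session_length_s / config.bin_length_s))
    w, feeding = _state_weights(intervals, n_bins, config.bin_length_s, config.ramp_length_s)
    shrink_set = _shrink_features(config)
    names = spec.feature_names()
    x = rng.standard_normal((n_bins, len(names)))
    sd = np.where(feeding, config.variance_shrink, 1.0)
    for j, f in enumerate(names):
        if f in shrink_set:
            x[:, j] *= sd
        d = effects.get(f, 0.0)
        if d:
            x[:, j] += w * d
    table = pd.DataFrame(x, columns=names)
    table.insert(0, "bin_start_s", np.arange(n_bins) * config.bin_length_s)
    return table


def generate_feature_cohort(
    config: CohortConfig,
    spec: FeatureSpec | None = None,
    label_cfg: LabelConfig | None = None,
) -> list[SyntheticSession]:
    """Generate the cohort directly at the binned-feature level.

    Features are unit-variance Gaussian per bin with the planted state
    shifts, ramp, variance shrink, and random effects — the downstream
    modeling layers see the same statistical structure as from the
    signal path, at a fraction of the cost.  Tables come back labeled.
    """
    config.validate()
    spec = spec or FeatureSpec()
    label_cfg = label_cfg or LabelConfig(bin_length_s=config.bin_length_s)
    root = np.random.default_rng(np.random.SeedSequence(config.seed))
    animal_re, cond_re = _draw_random_effects(config, root)
    sessions = []
    for aid, cond, sid in _session_plan(config):
        rng = np.random.default_rng(root.bit_generator.random_raw(2))
        intervals = generate_behavior_schedule(config, cond, rng)
        effects = _session_effects(config, cond, animal_re[aid], cond_re.get(cond, {}))
        meta = _make_meta(config, aid, cond, sid, effects, rng)
        effects = _apply_chew_confound(config, effects, meta, intervals)
        table = _feature_bins(config, spec, intervals, effects, rng)
        table = label_bins(table, intervals, label_cfg)
        table["animal_id"] = aid
        table["condition"] = cond
        table["session_id"] = sid
        sessions.append(SyntheticSession(meta=meta, intervals=intervals, features=table))
    return sessions


# ---------------------------------------------------------------------------
# signal-level generation
# ---------------------------------------------------------------------------

def _band_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return (x / s if s > 0 else x).astype(np.float32)


def _synthesize_signal(
    config: CohortConfig,
    spec: FeatureSpec,
    intervals: BehaviorIntervals,
    effects: dict[str, float],
    rng: np.random.Generator,
) -> SessionRecording:
    """Sum of band-limited carriers with per-bin envelopes.

    Per channel and band the carrier is a mix of a band-shared
    component and private noise; the mixing fraction sets pair
    coherence and the per-bin amplitude sets band power.  Planted
    shifts act on log2 band power (power features) or on the logit of
    the shared fraction for both channels of the pair (coherence
    features).
    """
    fs = config.sampling_rate_hz
    n = int(round(config.session_length_s * fs))
    n_bins = int(round(config.session_length_s / config.bin_length_s))
    spb = int(round(config.bin_length_s * fs))
    w, feeding = _state_weights(intervals, n_bins, config.bin_length_s, config.ramp_length_s)
    shrink = np.where(feeding, config.variance_shrink, 1.0)
    shrink_set = _shrink_features(config)
    channels = spec.layout.channels
    lp_scale = 0.5  # SD of log2 band power across bins, outside feeding
    coh_scale = 0.6
    rho0 = 0.30  # baseline shared-variance fraction per channel/band

    out = np.zeros((len(channels), n_bins * spb), dtype=np.float32)
    for b in spec.bands:
        shared = _band_noise(n, b.lo_hz, b.hi_hz, fs, rng)[: n_bins * spb]
        # per-pair latent coherence modulation for this band
        pair_lat: dict[tuple[str, str], np.ndarray] = {}
        for c1, c2 in spec.layout.pairs:
            name = f"{c1}{c2}{b.code}"
            d = effects.get(name, 0.0)
            e = rng.standard_normal(n_bins) * (shrink if name in shrink_set else 1.0)
            pair_lat[(c1, c2)] = coh_scale * (w * d + 0.3 * e) if d else np.zeros(n_bins)
        for ci, ch in enumerate(channels):
            name = f"{ch}{b.code}"
            d_pow = effects.get(name, 0.0)
            z = w * d_pow + rng.standard_normal(n_bins) * (shrink if name in shrink_set else 1.0)
            amp = np.exp2(0.5 * lp_scale * z).astype(np.float32)
            lat = np.full(n_bins, np.log(rho0 / (1 - rho0)))
            for (c1, c2), v in pair_lat.items():
                if ch in (c1, c2):
                    lat = lat + 0.5 * v
            rho = 1.0 / (1.0 + np.exp(-lat))
            mix_s = np.sqrt(rho).astype(np.float32)
            mix_n = np.sqrt(1.0 - rho).astype(np.float32)
            priv = _band_noise(n, b.lo_hz, b.hi_hz, fs, rng)[: n_bins * spb]
            carrier = (
                np.repeat(mix_s, spb) * shared + np.repeat(mix_n, spb) * priv
            )
            out[ci] += np.repeat(amp, spb) * carrier
    return SessionRecording(out, sampling_rate_hz=fs, channel_names=tuple(channels))


def generate_cohort(
    config: CohortConfig,
    spec: FeatureSpec | None = None,
    signals: bool = True,
) -> list[SyntheticSession]:
    """Generate the full synthetic cohort.

    One session per animal x condition (plus ``n_base_sessions`` Base
    recordings per animal).  With ``signals=True`` each session carries
    a continuous 4-channel recording whose per-bin band power and
    coherence follow the planted effect table, ramp, and variance
    shrink; with ``signals=False`` this is ``generate_feature_cohort``.
    Identical config and seed reproduce the cohort byte for byte.
    """
    if not signals:
        return generate_feature_cohort(config, spec)
    config.validate()
    spec = spec or FeatureSpec()
    root = np.random.default_rng(np.random.SeedSequence(config.seed))
    animal_re, cond_re = _draw_random_effects(config, root)
    sessions = []
    for aid, cond, sid in _session_plan(config):
        rng = np.random.default_rng(root.bit_generator.random_raw(2))
        intervals = generate_behavior_schedule(config, cond, rng)
        effects = _session_effects(config, cond, animal_re[aid], cond_re.get(cond, {}))
        meta = _make_meta(config, aid, cond, sid, effects, rng)
        effects = _apply_chew_confound(config, effects, meta, intervals)
        rec = _synthesize_signal(config, spec, intervals, effects, rng)
        sessions.append(SyntheticSession(meta=meta, intervals=intervals, recording=rec))
    return sessions


def cohort_table(sessions: list[SyntheticSession]) -> pd.DataFrame:
    """Concatenate labeled per-session feature tables into one frame."""
    frames = []
    for s in sessions:
        if s.features is None:
            raise ValueError(f"session {s.meta.session_id} has no feature table")
        frames.append(s.features)
    return pd.concat(frames, ignore_index=True)
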