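"""Assign 5-s bins to behavioral categories from scored intervals.

Every bin gets exactly one label: ``feeding`` (overlaps a scored
feeding interval), ``prefeed`` (lies in the 45-s window before a
feeding onset and does not touch any earlier feeding epoch), or
``notfeed``.  Bins overlapping scored rest intervals additionally carry
a ``rest`` flag (rest is a sub-category of not-feeding).  Pre-feeding
bins record their lag: bin-center seconds before onset, on the grid
2.5, 7.5, ..., 42.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorIntervals",
    "LabelConfig",
    "BehaviorSummary",
    "label_bins",
    "approach_overlap_by_lag",
    "behavior_summary",
    "PREFEED_LAGS",
]


@dataclass
class BehaviorIntervals:
    """Scored intervals: (start_s, end_s, label) with label in
    {feeding, approach, rest}; times half-open [start, end)."""

    intervals: pd.DataFrame  # columns start_s, end_s, label
    session_length_s: float

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"])
        if len(df):
            if (df.start_s < 0).any() or (df.end_s > self.session_length_s + 1e-9).any():
                raise ValueError("interval outside [0, session_length]")
            if (df.start_s >= df.end_s).any():
                raise ValueError("interval with start >= end")
            feed = df[df.label == "feeding"].sort_values("start_s")
            if (feed.start_s.values[1:] < feed.end_s.values[:-1]).any():
                raise ValueError("overlapping feeding intervals")
        self.intervals = df.sort_values("start_s").reset_index(drop=True)

    def of(self, label: str) -> pd.DataFrame:
        return self.intervals[self.intervals.label == label]

    @classmethod
    def from_csv(cls, path, session_length_s: float) -> "BehaviorIntervals":
        return cls(pd.read_csv(path), session_length_s)

    def to_csv(self, path) -> None:
        self.intervals.to_csv(path, index=False)


@dataclass(frozen=True)
class LabelConfig:
    prefeeding_window_s: float = 45.0
    bin_length_s: float = 5.0
    min_epoch_for_perievent_s: float = 45.0

    def __post_init__(self) -> None:
        n = self.prefeeding_window_s / self.bin_length_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("prefeeding_window_s must be divisible by bin_length_s")

    @property
    def n_lags(self) -> int:
        return int(round(self.prefeeding_window_s / self.bin_length_s))

    @property
    def lags(self) -> np.ndarray:
        """Bin-center lags before onset: 2.5, 7.5, ..., 42.5 s by default."""
        return self.bin_length_s / 2 + self.bin_length_s * np.arange(self.n_lags)


PREFEED_LAGS = LabelConfig().lags


def _overlaps(starts: np.ndarray, ends: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean: which [starts, ends) intervals overlap [lo, hi)."""
    return (starts < hi) & (ends > lo)


def label_bins(
    table: pd.DataFrame,
    intervals: BehaviorIntervals,
    cfg: LabelConfig | None = None,
) -> pd.DataFrame:
    """Attach label / rest / lag_s columns to a binned feature table.

    A bin touching any feeding interval is ``feeding`` (any-overlap
    rule).  Otherwise it is ``prefeed`` if its center falls within the
    45-s window before some feeding onset and the bin does not overlap
    an earlier feeding epoch; the lag is the onset minus bin center.
    Everything else is ``notfeed``; those overlapping a rest interval
    get rest=True.
    """
    cfg = cfg or LabelConfig()
    out = table.copy()
    bl = cfg.bin_length_s
    starts = out["bin_start_s"].to_numpy(dtype=float)
    ends = starts + bl
    centers = starts + bl / 2

    feed = intervals.of("feeding")
    fs, fe = feed.start_s.to_numpy(), feed.end_s.to_numpy()
    rest = intervals.of("rest")
    rs, re = rest.start_s.to_numpy(), rest.end_s.to_numpy()

    labels = np.full(len(out), "notfeed", dtype=object)
    lag = np.full(len(out), np.nan)

    for i in range(len(out)):
        if _overlaps(fs, fe, starts[i], ends[i]).any():
            labels[i] = "feeding"
            continue
        # candidate onsets whose pre-window contains the bin center
        cand = fs[(centers[i] < fs) & (centers[i] > fs - cfg.prefeeding_window_s)]
        if len(cand):
            onset = cand.min()
            # discard if the bin overlaps any earlier feeding epoch
            earlier = fe <= onset + 1e-9
            if not _overlaps(fs[earlier], fe[earlier], starts[i], ends[i]).any():
                labels[i] = "prefeed"
                # snap to the bin-center grid: 2.5, 7.5, ..., 42.5 s
                raw = onset - centers[i]
                lag[i] = bl / 2 + bl * min(np.floor(raw / bl), cfg.n_lags - 1)
    is_rest = np.zeros(len(out), dtype=bool)
    if len(rs):
        for i in range(len(out)):
            if labels[i] == "notfeed" and _overlaps(rs, re, starts[i], ends[i]).any():
                is_rest[i] = True

    out["label"] = labels
    out["rest"] = is_rest
    out["lag_s"] = lag
    return out


def approach_overlap_by_lag(
    labeled: pd.DataFrame,
    intervals: BehaviorIntervals,
    cfg: LabelConfig | None = None,
) -> pd.Series:
    """Percent of pre-feeding bins at each lag overlapping approach behavior."""
    cfg = cfg or LabelConfig()
    app = intervals.of("approach")
    a_s, a_e = app.start_s.to_numpy(), app.end_s.to_numpy()
    pre = labeled[labeled.label == "prefeed"]
    out = {}
    for lag in cfg.lags:
        rows = pre[np.isclose(pre.lag_s, lag)]
        if len(rows) == 0:
            out[lag] = np.nan
            continue
        s = rows.bin_start_s.to_numpy(dtype=float)
        hits = np.array([_overlaps(a_s, a_e, lo, lo + cfg.bin_length_s).any() for lo in s])
        out[lag] = 100.0 * hits.mean()
    ser = pd.Series(out)
    ser.index.name = "lag_s"
    return ser


@dataclass
class BehaviorSummary:
    animal_id: str
    condition: str
    kcal_consumed: float
    total_feeding_time_s: float
    voracity_kcal_per_min: float
    normalized_feeding_curve: pd.Series | None = None


def behavior_summary(intervals: BehaviorIntervals, meta, n_curve: int = 100) -> BehaviorSummary:
    """Session-level behavioral summary.

    Voracity is kcal consumed per minute of scored feeding.  The
    normalized feeding curve is feeding occupancy on a session-length-
    normalized time grid (for comparing feeding dynamics across
    sessions of unequal length).
    """
    feed = intervals.of("feeding")
    total = float((feed.end_s - feed.start_s).sum())
    kcal = float(meta.kcal_consumed)
    if total == 0:
        if kcal > 0:
            raise ValueError("nonzero kcal with zero scored feeding time")
        voracity = 0.0
    else:
        voracity = kcal / (total / 60.0)
    grid = np.linspace(0, 1, n_curve, endpoint=False)
    t = grid * intervals.session_length_s
    feeding = np.zeros(n_curve, dtype=bool)
    for s, e in zip(feed.start_s, feed.end_s):
        feeding |= (t >= s) & (t < e)
    curve = pd.Series(feeding.astype(float), index=grid)
    return BehaviorSummary(
        animal_id=meta.animal_id,
        condition=meta.condition,
        kcal_consumed=kcal,
        total_feeding_time_s=total,
        voracity_kcal_per_min=voracity,
        normalized_feeding_curve=curve,
    )
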