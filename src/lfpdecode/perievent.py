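"""Peri-feeding-event feature trajectories.

Feeding epochs lasting at least 45 s are aligned at onset (window
-62.5 s .. +32.5 s, 19 bins) and at offset (-12.5 s .. +52.5 s, 13
bins); the minimum-duration rule keeps a bin from appearing in both
alignments of one epoch.  Outside-feeding bins that overlap any other
feeding epoch are excluded.  The module exposes the mean +/- SD trace
per aligned bin (the "ramping" picture) and the feeding vs non-feeding
variance comparison (the variance-collapse picture).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import BehaviorIntervals

__all__ = [
    "PeriEventConfig",
    "AlignedEpochs",
    "collect_epochs",
    "perievent_average",
    "variance_change",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeriEventConfig:
    pre_onset_s: float = 62.5
    post_onset_s: float = 32.5
    pre_offset_s: float = 12.5
    post_offset_s: float = 52.5
    min_epoch_s: float = 45.0
    bin_length_s: float = 5.0

    def __post_init__(self) -> None:
        for pre, post in ((self.pre_onset_s, self.post_onset_s),
                          (self.pre_offset_s, self.post_offset_s)):
            v = (pre + post) / self.bin_length_s
            if abs(v - round(v)) > 1e-9:
                raise ValueError("peri-event window must span a whole number of bins")

    @property
    def onset_bins(self) -> int:
        return int(round((self.pre_onset_s + self.post_onset_s) / self.bin_length_s))

    @property
    def offset_bins(self) -> int:
        return int(round((self.pre_offset_s + self.post_offset_s) / self.bin_length_s))


@dataclass
class AlignedEpochs:
    """Feature values on the aligned bin grids; NaN where excluded."""

    onset: np.ndarray  # (n_epochs, onset_bins)
    offset: np.ndarray  # (n_epochs, offset_bins)
    onset_offsets_s: np.ndarray  # bin-center time relative to onset
    offset_offsets_s: np.ndarray
    onset_is_feeding: np.ndarray  # bool per aligned bin
    offset_is_feeding: np.ndarray
    feature: str


def _epoch_rows(
    table: pd.DataFrame, centers_rel: np.ndarray, anchor: float, feature: str,
    fs: np.ndarray, fe: np.ndarray, epoch: tuple[float, float], bin_length: float,
) -> np.ndarray:
    """Feature values at bins centered at anchor + centers_rel; NaN when
    the bin is absent or overlaps a different feeding epoch."""
    out = np.full(len(centers_rel), np.nan)
    starts = table.bin_start_s.to_numpy(dtype=float)
    vals = table[feature].to_numpy(dtype=float)
    for j, rel in enumerate(centers_rel):
        c = anchor + rel
        lo = np.floor(c / bin_length) * bin_length  # bin containing time c
        i = np.flatnonzero(np.isclose(starts, lo, atol=bin_length / 4))
        if len(i) == 0 or c < 0:
            continue
        hi = lo + bin_length
        other = (fs < hi) & (fe > lo) & ~((fs == epoch[0]) & (fe == epoch[1]))
        if other.any():
            continue
        out[j] = vals[i[0]]
    return out


def collect_epochs(
    table: pd.DataFrame,
    intervals: BehaviorIntervals,
    feature: str,
    cfg: PeriEventConfig | None = None,
) -> AlignedEpochs:
    """Align one feature around feeding onsets and offsets.

    Epochs shorter than ``min_epoch_s`` are dropped; bins overlapping a
    different feeding epoch are NaN-masked.  Returns empty matrices
    (with a warning) when no epoch qualifies.
    """
    cfg = cfg or PeriEventConfig()
    bl = cfg.bin_length_s
    feed = intervals.of("feeding")
    fs, fe = feed.start_s.to_numpy(), feed.end_s.to_numpy()
    qual = [(s, e) for s, e in zip(fs, fe) if e - s >= cfg.min_epoch_s]
    on_rel = -cfg.pre_onset_s + bl / 2 + bl * np.arange(cfg.onset_bins)
    off_rel = -cfg.pre_offset_s + bl / 2 + bl * np.arange(cfg.offset_bins)
    if not qual:
        logger.warning("no feeding epochs >= %.0f s; empty peri-event result", cfg.min_epoch_s)
        return AlignedEpochs(
            np.empty((0, cfg.onset_bins)), np.empty((0, cfg.offset_bins)),
            on_rel, off_rel, on_rel >= 0, off_rel < 0, feature,
        )
    onset_rows, offset_rows = [], []
    for s, e in qual:
        onset_rows.append(_epoch_rows(table, on_rel, s, feature, fs, fe, (s, e), bl))
        offset_rows.append(_epoch_rows(table, off_rel, e, feature, fs, fe, (s, e), bl))
    return AlignedEpochs(
        onset=np.vstack(onset_rows),
        offset=np.vstack(offset_rows),
        onset_offsets_s=on_rel,
        offset_offsets_s=off_rel,
        onset_is_feeding=on_rel >= 0,
        offset_is_feeding=off_rel < 0,
        feature=feature,
    )


def perievent_average(aligned: AlignedEpochs) -> pd.DataFrame:
    """Mean and across-epoch SD per aligned bin, plus reference levels.

    Returns a tidy frame (alignment, offset_s, mean, sd, n); reference
    feeding / non-feeding levels are the means over the feeding vs
    non-feeding portions of the aligned windows.
    """
    if len(aligned.onset) < 2:
        raise ValueError("need at least 2 epochs for a peri-event average")
    rows = []
    for name, mat, offs in (
        ("onset", aligned.onset, aligned.onset_offsets_s),
        ("offset", aligned.offset, aligned.offset_offsets_s),
    ):
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1)
        n = (~np.isnan(mat)).sum(axis=0)
        for j in range(mat.shape[1]):
            rows.append((name, offs[j], mean[j], sd[j], int(n[j])))
    return pd.DataFrame(rows, columns=["alignment", "offset_s", "mean", "sd", "n"])


def variance_change(
    aligned: AlignedEpochs, min_bins: int = 10
) -> tuple[float, float, float]:
    """SD ratio (feeding / non-feeding) over the aligned bins, with a
    Levene test.  Returns (ratio, levene_W, p)."""
    feed = np.concatenate(
        [aligned.onset[:, aligned.onset_is_feeding].ravel(),
         aligned.offset[:, aligned.offset_is_feeding].ravel()]
    )
    non = np.concatenate(
        [aligned.onset[:, ~aligned.onset_is_feeding].ravel(),
         aligned.offset[:, ~aligned.offset_is_feeding].ravel()]
    )
    feed = feed[~np.isnan(feed)]
    non = non[~np.isnan(non)]
    if len(feed) < min_bins or len(non) < min_bins:
        logger.warning("variance_change: low power (feeding=%d, non=%d bins)", len(feed), len(non))
    if len(feed) < 2 or len(non) < 2:
        raise ValueError("need at least 2 bins per state")
    ratio = float(np.std(feed, ddof=1) / np.std(non, ddof=1))
    w, p = stats.levene(feed, non)
    return ratio, float(w), float(p)
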