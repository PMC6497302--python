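"""Spectral feature extraction: per-bin band power and coherence.

A session recording is cut into non-overlapping 5-second bins; within
each bin, power spectral densities and magnitude-squared coherences are
estimated by Welch's method (1-s Hann segments, 50% overlap) and
summarized per band: power as the integral of the PSD over the band,
coherence as the mean MSC across band frequencies.

All bins are processed in one vectorized pass (the bin axis rides along
scipy's FFT axis broadcasting), so full-session extraction is cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import Band, FeatureSpec

__all__ = [
    "SessionRecording",
    "bin_signal",
    "band_power",
    "band_coherence",
    "build_feature_table",
    "normalize_for_plot",
    "META_COLUMNS",
]

logger = logging.getLogger(__name__)

#: non-feature columns of a binned feature table
META_COLUMNS = ["bin_start_s", "label", "rest", "lag_s", "animal_id", "condition"]


@dataclass
class SessionRecording:
    """Continuous multichannel signal with its sampling rate and layout."""

    data: np.ndarray  # shape (n_channels, n_samples)
    sampling_rate_hz: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate_hz


def _welch_params(fs: float) -> dict:
    nperseg = int(round(fs))  # 1-s segments -> 1 Hz resolution
    return dict(fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann", detrend="constant")


def bin_signal(recording: SessionRecording, spec: FeatureSpec) -> np.ndarray:
    """Cut the recording into non-overlapping bins.

    Returns an array of shape (n_bins, n_channels, samples_per_bin);
    any trailing remainder shorter than one bin is dropped.  A recording
    shorter than one bin yields zero windows with a warning.
    """
    fs = recording.sampling_rate_hz
    n_bin = fs * spec.bin_length_s
    if abs(n_bin - round(n_bin)) > 1e-9:
        raise ValueError("sampling_rate * bin_length must be an integer sample count")
    n_bin = int(round(n_bin))
    n_samples = recording.data.shape[1]
    n_windows = n_samples // n_bin
    if n_windows == 0:
        warnings.warn("recording shorter than one bin; no windows produced", stacklevel=2)
        return np.empty((0, recording.data.shape[0], n_bin))
    trimmed = recording.data[:, : n_windows * n_bin]
    # (channels, bins, samples) -> (bins, channels, samples)
    return trimmed.reshape(recording.data.shape[0], n_windows, n_bin).transpose(1, 0, 2)


def _band_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    return (freqs >= band.lo_hz) & (freqs <= band.hi_hz)


def band_power(window: np.ndarray, fs: float, band: Band) -> float | np.ndarray:
    """Band power of one (or a stack of) single-channel window(s).

    Integral of the Welch PSD over [lo_hz, hi_hz] (trapezoid rule on the
    1-Hz Welch grid), in signal-units^2.
    """
    if band.hi_hz >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
    freqs, psd = sps.welch(np.asarray(window, dtype=float), axis=-1, **_welch_params(fs))
    m = _band_mask(freqs, band)
    return np.trapezoid(psd[..., m], freqs[m], axis=-1)


def band_coherence(x: np.ndarray, y: np.ndarray, fs: float, band: Band) -> float | np.ndarray:
    """Mean magnitude-squared coherence between two channels over a band.

    Raises for zero-variance input (coherence undefined there).
    """
    if band.hi_hz >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.std(x, axis=-1) == 0) or np.any(np.std(y, axis=-1) == 0):
        raise ValueError("zero-variance channel: coherence undefined")
    freqs, coh = sps.coherence(x, y, axis=-1, **_welch_params(fs))
    m = _band_mask(freqs, band)
    return coh[..., m].mean(axis=-1)


def build_feature_table(recording: SessionRecording, spec: FeatureSpec) -> pd.DataFrame:
    """Per-bin feature matrix for one session.

    Returns a DataFrame with one row per 5-s bin: ``bin_start_s`` plus
    one column per feature (power columns first, channels outer / bands
    inner; then coherence columns, pairs outer / bands inner), with the
    spec's exclusions dropped.  Bins containing NaN samples or a
    zero-variance channel are excluded (and logged), never imputed.
    """
    fs = recording.sampling_rate_hz
    for b in spec.bands:
        if b.hi_hz >= fs / 2:
            raise ValueError(f"band {b.name} exceeds Nyquist ({fs / 2} Hz)")
    windows = bin_signal(recording, spec)  # (bins, channels, samples)
    n_bins = windows.shape[0]
    bin_starts = np.arange(n_bins) * spec.bin_length_s

    ch_index = {ch: recording.channel_names.index(ch) for ch in spec.layout.channels}
    valid = ~np.isnan(windows).any(axis=(1, 2))
    valid &= (windows.std(axis=2) > 0).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("excluding %d invalid bins (NaN or zero variance)", n_bad)

    wp = _welch_params(fs)
    vw = windows[valid]
    freqs, psd = sps.welch(vw, axis=-1, **wp)  # psd: (vbins, channels, freqs)
    masks = {b.name: _band_mask(freqs, b) for b in spec.bands}

    cols: dict[str, np.ndarray] = {}
    for ch in spec.layout.channels:
        p = psd[:, ch_index[ch], :]
        for b in spec.bands:
            m = masks[b.name]
            cols[f"{ch}{b.code}"] = np.trapezoid(p[:, m], freqs[m], axis=-1)
    for c1, c2 in spec.layout.pairs:
        x = vw[:, ch_index[c1], :]
        y = vw[:, ch_index[c2], :]
        _, coh = sps.coherence(x, y, axis=-1, **wp)
        for b in spec.bands:
            cols[f"{c1}{c2}{b.code}"] = coh[:, masks[b.name]].mean(axis=-1)

    table = pd.DataFrame(cols, index=np.arange(n_bins)[valid])
    table = table[spec.feature_names()]
    table.insert(0, "bin_start_s", bin_starts[valid])
    return table.reset_index(drop=True)


def normalize_for_plot(table: pd.DataFrame, feature: str, spec: FeatureSpec) -> pd.Series:
    """Per-bin display normalization of one feature.

    Power features are divided by that channel's per-bin total power
    (sum over the spec's bands); coherence features by the per-bin mean
    coherence across bands for that pair.  Bins with a zero denominator
    come back NaN.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    chans = spec.channels_of(feature)
    if spec.is_power(feature):
        sibling = [f"{chans[0]}{b.code}" for b in spec.bands]
        denom = table[[c for c in sibling if c in table.columns]].sum(axis=1)
    else:
        head = chans[0] + chans[1]
        sibling = [f"{head}{b.code}" for b in spec.bands]
        denom = table[[c for c in sibling if c in table.columns]].mean(axis=1)
    denom = denom.where(denom != 0)
    return table[feature] / denom
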