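"""Figure helpers: peri-event traces and performance distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_perievent_trace", "plot_performance", "plot_backtest"]


def plot_perievent_trace(traces: pd.DataFrame, feature: str, path: Path) -> None:
    """Mean +/- 1 SD of a feature around feeding onset and offset."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    sub = traces[traces.feature == feature] if "feature" in traces else traces
    for ax, name, title in zip(axes, ["onset", "offset"], ["feeding onset", "feeding offset"]):
        d = sub[sub.alignment == name]
        ax.fill_between(d.offset_s, d["mean"] - d.sd, d["mean"] + d.sd, alpha=0.3)
        ax.plot(d.offset_s, d["mean"], lw=1.5)
        ax.axvline(0, color="k", ls="--", lw=0.8)
        ax.set_title(title)
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_performance(samples: dict[str, np.ndarray], path: Path, metric: str = "AUC") -> None:
    """Mean with 95% CI per labeled performance distribution."""
    fig, ax = plt.subplots(figsize=(1.2 * len(samples) + 1.5, 3))
    for i, (label, s) in enumerate(samples.items()):
        lo, hi = np.percentile(s, [2.5, 97.5])
        ax.errorbar(i, np.mean(s), yerr=[[np.mean(s) - lo], [hi - np.mean(s)]],
                    fmt="o", capsize=4)
    ax.set_xticks(range(len(samples)), list(samples), rotation=30, ha="right")
    ax.set_ylabel(metric)
    if metric == "AUC":
        ax.axhline(0.5, color="grey", ls=":", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_backtest(back: pd.DataFrame, path: Path) -> None:
    """AUC vs pre-feeding lag (bin-center seconds before onset)."""
    g = back.groupby("lag_s").auc.agg(["mean", lambda s: s.quantile(0.025),
                                       lambda s: s.quantile(0.975)])
    g.columns = ["mean", "lo", "hi"]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.errorbar(g.index, g["mean"], yerr=[g["mean"] - g.lo, g.hi - g["mean"]],
                fmt="o-", capsize=3)
    ax.axhline(0.5, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("lag before feeding onset (s)")
    ax.set_ylabel("AUC")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
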