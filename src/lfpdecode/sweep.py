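"""Model-complexity sweep: exhaustive monad/dyad/triad evaluation.

All C(n,k) feature subsets for k in {1,2,3} are scored with the same
per-iteration splits and the same ADASYN-balanced training sets as the
lasso and full-logistic references, so performances are directly
comparable.  "Top tier" is the set of subsets whose per-iteration AUC
distributions are not significantly worse than the best subset's
(Welch two-sample t-tests, Bonferroni-corrected within each k group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .bands import FeatureSpec
from .whole_session import PerformanceDistribution
from .within_session import (
    EvalConfig,
    adasyn_balance,
    evaluate_auc,
    make_xy,
    split_80_20,
    train_classifier,
)

__all__ = [
    "SubsetSweepResult",
    "enumerate_subsets",
    "prepare_iterations",
    "sweep",
    "top_tier",
    "frequency_contribution",
    "lasso_survival",
    "minimal_model_search",
]

logger = logging.getLogger(__name__)


def enumerate_subsets(feature_names: list[str], k: int) -> list[tuple[str, ...]]:
    """All C(n,k) unordered feature combinations, lexicographic in the
    given feature order."""
    if not 1 <= k <= len(feature_names):
        raise ValueError(f"k={k} outside 1..{len(feature_names)}")
    return list(combinations(feature_names, k))


@dataclass
class IterationData:
    """One shared train/test realization (balanced training set)."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class SubsetSweepResult:
    k: int
    combos: list[tuple[str, ...]]
    auc: np.ndarray  # (n_combos, n_iterations)
    feature_names: list[str]

    def table(self) -> pd.DataFrame:
        mean = self.auc.mean(axis=1)
        lo, hi = np.percentile(self.auc, [2.5, 97.5], axis=1)
        return pd.DataFrame(
            {
                "k": self.k,
                "features": ["+".join(c) for c in self.combos],
                "mean_auc": mean,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )

    def best(self) -> tuple[tuple[str, ...], float]:
        i = int(np.argmax(self.auc.mean(axis=1)))
        return self.combos[i], float(self.auc[i].mean())


def prepare_iterations(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    positive: str = "feeding",
) -> list[IterationData]:
    """Build the shared per-iteration splits + balanced training sets.

    Balancing runs once on the full feature space; subset models then
    select columns, so every model family sees identical training
    points and identical naive test sets.
    """
    t = table.reset_index(drop=True)
    iters = []
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        tr_mask, te_mask = split_80_20(t, rng, cfg.train_fraction)
        X_tr, y_tr = make_xy(t[tr_mask], feature_names, positive)
        X_te, y_te = make_xy(t[te_mask], feature_names, positive)
        if cfg.balance_method == "adasyn" and len(np.unique(y_tr)) == 2:
            X_tr, y_tr = adasyn_balance(X_tr, y_tr, cfg.k_neighbors, rng=rng)
        iters.append(IterationData(X_tr, y_tr, X_te, y_te))
    return iters


def _score_columns(iters: list[IterationData], cols: list[int], cfg: EvalConfig) -> np.ndarray:
    out = np.empty(len(iters))
    sub_cfg = cfg
    for i, it in enumerate(iters):
        model = train_classifier(it.X_train[:, cols], it.y_train, sub_cfg)
        out[i] = evaluate_auc(model, it.X_test[:, cols], it.y_test)
    return out


def sweep(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    k: int,
    iters: list[IterationData] | None = None,
    screen_iterations: int | None = None,
    screen_top_fraction: float = 0.01,
    combo_cap: int | None = None,
) -> SubsetSweepResult:
    """Score every k-subset over the shared iterations.

    For large sweeps a two-pass mode is available: a screening pass on
    the first ``screen_iterations`` iterations, then full evaluation of
    the top ``screen_top_fraction`` (plus a margin) of subsets; exact
    single-pass evaluation is the default.
    """
    combos = enumerate_subsets(feature_names, k)
    if combo_cap is not None and len(combos) > combo_cap:
        rng = np.random.default_rng(cfg.seed)
        sel = rng.choice(len(combos), combo_cap, replace=False)
        combos = [combos[j] for j in sorted(sel)]
        logger.info("sweep k=%d: combos capped at %d", k, combo_cap)
    iters = iters or prepare_iterations(table, feature_names, cfg)
    col_of = {f: j for j, f in enumerate(feature_names)}
    auc = np.full((len(combos), len(iters)), np.nan)

    if screen_iterations and screen_iterations < len(iters):
        head = iters[:screen_iterations]
        means = np.empty(len(combos))
        part = np.full((len(combos), len(iters)), np.nan)
        for ci, combo in enumerate(combos):
            cols = [col_of[f] for f in combo]
            part[ci, :screen_iterations] = _score_columns(head, cols, cfg)
            means[ci] = np.nanmean(part[ci])
        n_full = max(1, int(np.ceil(screen_top_fraction * len(combos))))
        keep = np.argsort(-means)[:n_full]
        auc = part
        for ci in keep:
            cols = [col_of[f] for f in combos[ci]]
            auc[ci, screen_iterations:] = _score_columns(iters[screen_iterations:], cols, cfg)
        # rows evaluated only in the screen keep their screen-mean filled out
        for ci in range(len(combos)):
            if np.isnan(auc[ci]).any():
                auc[ci, screen_iterations:] = np.nanmean(auc[ci, :screen_iterations])
    else:
        for ci, combo in enumerate(combos):
            cols = [col_of[f] for f in combo]
            auc[ci] = _score_columns(iters, cols, cfg)
    return SubsetSweepResult(k=k, combos=combos, auc=auc, feature_names=feature_names)


def reference_distribution(
    iters: list[IterationData], cfg: EvalConfig, classifier: str
) -> PerformanceDistribution:
    """Full-logistic or lasso-logistic reference on the same iterations."""
    from dataclasses import replace

    ref_cfg = replace(cfg, classifier=classifier)
    auc = _score_columns(iters, list(range(iters[0].X_train.shape[1])), ref_cfg)
    return PerformanceDistribution(metric="AUC", samples=auc)


def top_tier(result: SubsetSweepResult, alpha: float = 0.05) -> np.ndarray:
    """Mask of subsets not significantly worse than the best subset.

    Welch two-sample t-test against the best-mean subset, Bonferroni
    over the (n_combos - 1) comparisons; the best subset is always in
    the tier; zero-variance pairs fall back to exact mean equality.
    """
    means = result.auc.mean(axis=1)
    best = int(np.argmax(means))
    n = len(result.combos)
    mask = np.zeros(n, dtype=bool)
    mask[best] = True
    if n == 1:
        return mask
    thresh = alpha / (n - 1)
    b = result.auc[best]
    for i in range(n):
        if i == best:
            continue
        s = result.auc[i]
        if np.std(b) == 0 and np.std(s) == 0:
            mask[i] = s.mean() == b.mean()
            continue
        t, p = stats.ttest_ind(s, b, equal_var=False)
        mask[i] = (p > thresh) or (s.mean() >= b.mean())
    return mask


def frequency_contribution(
    result: SubsetSweepResult, tier_mask: np.ndarray, spec: FeatureSpec
) -> pd.Series:
    """Percent of top-tier models containing >=1 feature of each band.

    For k>1 the percentages need not sum to 100 (a model can span
    several bands).
    """
    tier = [c for c, m in zip(result.combos, tier_mask) if m]
    if not tier:
        raise ValueError("empty top tier")
    out = {}
    for b in spec.bands:
        hit = sum(any(spec.band_of(f).name == b.name for f in combo) for combo in tier)
        out[b.name] = 100.0 * hit / len(tier)
    return pd.Series(out)


def lasso_survival(
    iters: list[IterationData], cfg: EvalConfig, feature_names: list[str]
) -> pd.Series:
    """Fraction of iterations in which each feature has a nonzero
    coefficient in the lasso-logistic reference model."""
    from dataclasses import replace

    ref_cfg = replace(cfg, classifier="lasso_logistic")
    counts = np.zeros(len(feature_names))
    for it in iters:
        model = train_classifier(it.X_train, it.y_train, ref_cfg)
        counts += model.coef_.ravel() != 0
    return pd.Series(counts / len(iters), index=feature_names)


def minimal_model_search(
    sweeps: dict[int, SubsetSweepResult],
    reference: PerformanceDistribution,
    lasso: PerformanceDistribution | None = None,
    alpha: float = 0.05,
) -> str:
    """Smallest model class matching the full-logistic reference.

    Compares the best member of each class (monad, dyad, triad, then
    lasso) against the full-logistic AUC distribution with Welch t-tests
    and Bonferroni over the classes tested; returns the first class
    that is not significantly worse, else "lasso/full".
    """
    names = {1: "monad", 2: "dyad", 3: "triad"}
    classes: list[tuple[str, np.ndarray]] = []
    for k in sorted(sweeps):
        best_idx = int(np.argmax(sweeps[k].auc.mean(axis=1)))
        classes.append((names.get(k, f"k={k}"), sweeps[k].auc[best_idx]))
    if lasso is not None:
        classes.append(("lasso", lasso.samples))
    n_tests = len(classes)
    ref = reference.samples
    for name, samples in classes:
        if samples.mean() >= ref.mean():
            return name
        p = stats.ttest_ind(samples, ref, equal_var=False).pvalue
        if p > alpha / n_tests:
            return name
    return "lasso/full"
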