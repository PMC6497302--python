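"""Bin-level classification: feeding / pre-feeding vs not-feeding.

Models are logistic regressions on 5-s-bin feature vectors, trained on
80% splits (stratified within animal and class), with ADASYN
oversampling of the rare positive class applied to training data only,
and evaluated as ROC AUC on the held-out naive test set.  Each
evaluation has a permuted twin (training labels shuffled) so that every
reported performance carries a matched chance distribution.

The generalization designs mirror the model-complexity questions:
population vs individual models, leave-k-animals-out, cross-condition
training/testing, and bins-per-animal learning curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .labeling import LabelConfig
from .whole_session import PerformanceDistribution

import warnings

__all__ = [
    "EvalConfig",
    "GeneralizationDesign",
    "adasyn_balance",
    "train_classifier",
    "evaluate_auc",
    "repeated_eval",
    "prefeeding_backtest",
    "animal_count_sweep",
    "individual_vs_population",
    "condition_generalization",
    "learning_curve",
    "make_xy",
    "split_80_20",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    train_fraction: float = 0.8
    n_iterations: int = 20
    balance_method: str = "adasyn"  # adasyn | class_weights | none
    classifier: str = "logistic"  # logistic | lasso_logistic
    k_neighbors: int = 5
    bins_per_animal: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class GeneralizationDesign:
    scheme: str = "population_all"  # population_all | leave_k_out | individual
    train_animals: tuple[str, ...] | None = None
    test_animals: tuple[str, ...] | None = None
    train_conditions: tuple[str, ...] | None = None
    test_conditions: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------

def adasyn_weights(
    X: np.ndarray, y: np.ndarray, k: int, minority
) -> np.ndarray:
    """Normalized ADASYN density weights r-hat per minority point: the
    majority fraction among each point's k nearest neighbors, normalized
    to sum to 1 (points in majority-dominated neighborhoods dominate)."""
    Xmin = X[y == minority]
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn_all.kneighbors(Xmin)
    neigh_labels = y[idx[:, 1:]]  # drop self
    r = (neigh_labels != minority).mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)  # no majority neighbors anywhere: spread evenly
    return r / r.sum()


def adasyn_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    beta: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    G = (N_maj - N_min) * beta synthetic points are allocated across
    minority points proportionally to the majority fraction among each
    point's k nearest neighbors (points in majority-dominated
    neighborhoods get the most), then generated by interpolation toward
    random minority neighbors.  Returns the augmented (X, y).
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("adasyn requires two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    G = int(round((n_maj - n_min) * beta))
    if G == 0:
        return X, y
    Xmin = X[y == minority]
    k = k_neighbors
    if n_min <= k:
        k = max(1, n_min - 1)
        logger.warning("adasyn: minority too small for k=%d, reduced to %d", k_neighbors, k)
    if k < 1:
        return X, y

    r = adasyn_weights(X, y, k, minority)
    g = np.floor(r * G).astype(int)
    # distribute the remainder to the highest-density points
    rem = G - g.sum()
    if rem > 0:
        g[np.argsort(-r)[:rem]] += 1

    # minority-only neighbor structure for interpolation partners
    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(Xmin))).fit(Xmin)
    _, midx = nn_min.kneighbors(Xmin)
    synth = []
    for i, gi in enumerate(g):
        if gi == 0:
            continue
        partners = midx[i, 1:] if midx.shape[1] > 1 else midx[i, :1]
        choice = rng.integers(0, len(partners), size=gi)
        lam = rng.random((gi, 1))
        synth.append(Xmin[i] + lam * (Xmin[partners[choice]] - Xmin[i]))
    if not synth:
        return X, y
    Xs = np.vstack(synth)
    ys = np.full(len(Xs), minority, dtype=y.dtype)
    return np.vstack([X, Xs]), np.concatenate([y, ys])


# ---------------------------------------------------------------------------
# classifiers and AUC
# ---------------------------------------------------------------------------

def train_classifier(X: np.ndarray, y: np.ndarray, cfg: EvalConfig):
    """Fit the configured classifier; exposes predict_proba."""
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes to train")
    kw = {}
    if cfg.balance_method == "class_weights":
        kw["class_weight"] = "balanced"
    if cfg.classifier == "lasso_logistic":
        model = LogisticRegressionCV(
            Cs=8, l1_ratios=[1.0], solver="liblinear", cv=5, max_iter=500,
            scoring="accuracy", **kw
        )
    else:
        # weak ridge keeps the fit defined under perfect separation
        model = LogisticRegression(C=1e4, max_iter=2000, **kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def evaluate_auc(model, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """ROC AUC of the model's positive-class probability (midrank ties)."""
    if len(np.unique(y_test)) < 2:
        raise ValueError("AUC undefined: test set has one class")
    scores = model.predict_proba(X_test)[:, 1]
    return float(roc_auc_score(y_test, scores))


# ---------------------------------------------------------------------------
# dataset helpers
# ---------------------------------------------------------------------------

def make_xy(
    table: pd.DataFrame,
    feature_names: list[str],
    positive: str = "feeding",
    lag: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and 0/1 labels for a classification task.

    ``positive='feeding'`` classifies feeding vs everything else
    outside feeding; ``positive='prefeed'`` (optionally at one lag)
    classifies pre-feeding bins vs not-feeding bins (rest included),
    with feeding bins excluded from the negatives.
    """
    if positive == "feeding":
        mask = table.label.isin(["feeding", "notfeed"])
        sub = table[mask]
        y = (sub.label == "feeding").to_numpy(dtype=int)
    elif positive == "prefeed":
        pos = table.label == "prefeed"
        if lag is not None:
            pos &= np.isclose(table.lag_s, lag)
        neg = table.label == "notfeed"
        sub = table[pos | neg]
        y = pos[pos | neg].to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown positive class {positive!r}")
    return sub[feature_names].to_numpy(dtype=float), y


def split_80_20(
    table: pd.DataFrame,
    rng: np.random.Generator,
    train_fraction: float = 0.8,
    by: tuple[str, ...] = ("animal_id", "label"),
) -> tuple[np.ndarray, np.ndarray]:
    """Index masks for a split stratified within animal and class."""
    train = np.zeros(len(table), dtype=bool)
    for _, grp in table.groupby(list(by), sort=True, dropna=False):
        idx = grp.index.to_numpy()
        idx = idx[rng.permutation(len(idx))]
        n_tr = int(round(train_fraction * len(idx)))
        train[table.index.get_indexer(idx[:n_tr])] = True
    test = ~train
    return train, test


def _fit_eval(
    X_tr, y_tr, X_te, y_te, cfg: EvalConfig, rng: np.random.Generator, permute: bool = False
) -> float:
    y_use = rng.permutation(y_tr) if permute else y_tr
    if cfg.balance_method == "adasyn" and len(np.unique(y_use)) == 2:
        X_use, y_use = adasyn_balance(X_tr, y_use, cfg.k_neighbors, rng=rng)
    else:
        X_use = X_tr
    model = train_classifier(X_use, y_use, cfg)
    return evaluate_auc(model, X_te, y_te)


# ---------------------------------------------------------------------------
# repeated evaluation
# ---------------------------------------------------------------------------

def repeated_eval(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    design: GeneralizationDesign | None = None,
    positive: str = "feeding",
    lag: float | None = None,
) -> PerformanceDistribution:
    """Repeated 80/20 (or leave-animal-out) evaluation with a permuted twin.

    Per iteration: split, balance the training data (only), train, and
    score AUC on the naive test set; the permuted pipeline is identical
    except training labels are shuffled before balancing.
    """
    design = design or GeneralizationDesign()
    rng = np.random.default_rng(cfg.seed)
    t = table
    if design.train_conditions and design.scheme != "leave_k_out":
        pass  # condition filtering handled by condition_generalization
    if design.scheme == "individual":
        if not design.train_animals or len(design.train_animals) != 1:
            raise ValueError("individual scheme requires exactly one train animal")
        t = t[t.animal_id == design.train_animals[0]]
    t = t.reset_index(drop=True)

    strat = ("animal_id", "label") if positive != "prefeed" else ("animal_id", "label", "lag_s")
    actual, permuted = [], []
    for i in range(cfg.n_iterations):
        it_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        if design.scheme == "leave_k_out":
            animals = sorted(t.animal_id.unique())
            held = design.test_animals or tuple(
                np.asarray(animals)[it_rng.choice(len(animals), 1, replace=False)]
            )
            tr_mask = ~t.animal_id.isin(held).to_numpy()
            te_mask = ~tr_mask
        else:
            tr_mask, te_mask = split_80_20(t, it_rng, cfg.train_fraction, by=strat)
        X_tr, y_tr = make_xy(t[tr_mask], feature_names, positive, lag)
        X_te, y_te = make_xy(t[te_mask], feature_names, positive, lag)
        try:
            actual.append(_fit_eval(X_tr, y_tr, X_te, y_te, cfg, it_rng))
            permuted.append(_fit_eval(X_tr, y_tr, X_te, y_te, cfg, it_rng, permute=True))
        except ValueError as e:
            logger.warning("iteration %d skipped: %s", i, e)
    if not actual:
        raise ValueError("no iteration produced a two-class train and test set")
    return PerformanceDistribution(
        metric="AUC", samples=np.asarray(actual), null_samples=np.asarray(permuted)
    )


# ---------------------------------------------------------------------------
# pre-feeding backtest
# ---------------------------------------------------------------------------

def prefeeding_backtest(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    label_cfg: LabelConfig | None = None,
) -> pd.DataFrame:
    """Train on the lag-2.5 pre-feeding bins vs not-feeding, then test on
    every lag's bins vs held-out not-feeding bins.

    Returns a frame (lag_s, iteration, auc); lags with no bins are NaN.
    """
    label_cfg = label_cfg or LabelConfig()
    lags = label_cfg.lags
    t = table.reset_index(drop=True)
    rows = []
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        tr_mask, te_mask = split_80_20(
            t, rng, cfg.train_fraction, by=("animal_id", "label", "lag_s")
        )
        X_tr, y_tr = make_xy(t[tr_mask], feature_names, "prefeed", lag=lags[0])
        if len(np.unique(y_tr)) < 2:
            continue
        if cfg.balance_method == "adasyn":
            X_tr, y_tr = adasyn_balance(X_tr, y_tr, cfg.k_neighbors, rng=rng)
        model = train_classifier(X_tr, y_tr, cfg)
        te = t[te_mask]
        neg = te[te.label == "notfeed"]
        for lag in lags:
            pos = te[(te.label == "prefeed") & np.isclose(te.lag_s, lag)]
            if len(pos) == 0 or len(neg) == 0:
                rows.append((lag, i, np.nan))
                continue
            X = np.vstack([pos[feature_names].to_numpy(float), neg[feature_names].to_numpy(float)])
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            rows.append((lag, i, evaluate_auc(model, X, y)))
    return pd.DataFrame(rows, columns=["lag_s", "iteration", "auc"])


# ---------------------------------------------------------------------------
# population / individual / condition designs
# ---------------------------------------------------------------------------

def animal_count_sweep(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    k_values: range | None = None,
    max_subsets: int = 30,
) -> pd.DataFrame:
    """Performance vs number of training animals.

    For each k, models are trained on all bins of k animals and tested
    on the held-out animals; all C(n,k) subsets are used unless that
    exceeds ``max_subsets``, in which case a seeded random subsample of
    subsets is drawn (and the cap logged).
    """
    animals = sorted(table.animal_id.unique())
    n = len(animals)
    k_values = k_values or range(1, n)
    rows = []
    rng = np.random.default_rng(cfg.seed)
    for k in k_values:
        if not 1 <= k <= n - 1:
            raise ValueError(f"k={k} outside 1..{n - 1}")
        combos = list(combinations(animals, k))
        if len(combos) > max_subsets:
            sel = rng.choice(len(combos), max_subsets, replace=False)
            combos = [combos[j] for j in sel]
            logger.info("animal_count_sweep: k=%d capped at %d subsets", k, max_subsets)
        for ci, combo in enumerate(combos):
            tr = table[table.animal_id.isin(combo)]
            te = table[~table.animal_id.isin(combo)]
            X_tr, y_tr = make_xy(tr, feature_names)
            X_te, y_te = make_xy(te, feature_names)
            it_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k, ci]))
            auc = _fit_eval(X_tr, y_tr, X_te, y_te, cfg, it_rng)
            rows.append((k, "+".join(combo), auc))
    return pd.DataFrame(rows, columns=["k_train", "train_animals", "auc"])


def individual_vs_population(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
) -> pd.DataFrame:
    """Paired per-animal differences: individual minus population AUC.

    Per iteration a single stratified 80/20 split is fixed and shared:
    the individual model (that animal's 80%), the population model (all
    animals' 80%), and the LOO population model (all bins of the other
    animals) are each tested on the same animal-specific 20% test bins.
    """
    t = table.reset_index(drop=True)
    animals = sorted(t.animal_id.unique())
    rows = []
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        tr_mask, te_mask = split_80_20(t, rng, cfg.train_fraction)
        X_pop, y_pop = make_xy(t[tr_mask], feature_names)
        if cfg.balance_method == "adasyn":
            X_pop_b, y_pop_b = adasyn_balance(X_pop, y_pop, cfg.k_neighbors, rng=rng)
        else:
            X_pop_b, y_pop_b = X_pop, y_pop
        pop_model = train_classifier(X_pop_b, y_pop_b, cfg)
        for aid in animals:
            te_a = t[te_mask & (t.animal_id == aid).to_numpy()]
            X_te, y_te = make_xy(te_a, feature_names)
            if len(np.unique(y_te)) < 2:
                logger.warning("animal %s iteration %d: one-class test set, skipped", aid, i)
                continue
            tr_ind = t[tr_mask & (t.animal_id == aid).to_numpy()]
            X_i, y_i = make_xy(tr_ind, feature_names)
            tr_loo = t[(t.animal_id != aid).to_numpy()]
            X_l, y_l = make_xy(tr_loo, feature_names)
            try:
                auc_ind = _fit_eval(X_i, y_i, X_te, y_te, cfg, rng)
                auc_pop = evaluate_auc(pop_model, X_te, y_te)
                auc_loo = _fit_eval(X_l, y_l, X_te, y_te, cfg, rng)
            except ValueError:
                continue
            rows.append((aid, i, auc_ind, auc_pop, auc_loo,
                         auc_ind - auc_pop, auc_ind - auc_loo))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "iteration", "auc_individual", "auc_population",
                 "auc_loo", "diff_vs_population", "diff_vs_loo"],
    )


def condition_generalization(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    train_conditions: tuple[str, ...] = ("Base",),
    test_conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Population and individual models trained on one condition set,
    tested on each condition's held-out bins.

    When training spans multiple conditions, bins per condition are
    equalized by subsampling.  Returns a tidy frame
    (scheme, test_condition, animal_id, iteration, auc).
    """
    t = table.reset_index(drop=True)
    test_conditions = test_conditions or tuple(sorted(t.condition.unique()))
    animals = sorted(t.animal_id.unique())
    rows = []
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        tr_mask, te_mask = split_80_20(t, rng, cfg.train_fraction)
        tr = t[tr_mask & t.condition.isin(train_conditions).to_numpy()]
        if len(train_conditions) > 1:
            n_min = tr.groupby("condition").size().min()
            parts = [
                g.sample(n=n_min, random_state=int(rng.integers(2**31)))
                for _, g in tr.groupby("condition", sort=True)
            ]
            tr = pd.concat(parts)
        X_p, y_p = make_xy(tr, feature_names)
        if cfg.balance_method == "adasyn":
            X_pb, y_pb = adasyn_balance(X_p, y_p, cfg.k_neighbors, rng=rng)
        else:
            X_pb, y_pb = X_p, y_p
        pop_model = train_classifier(X_pb, y_pb, cfg)
        ind_models = {}
        for aid in animals:
            tra = tr[tr.animal_id == aid]
            X_i, y_i = make_xy(tra, feature_names)
            if len(np.unique(y_i)) < 2:
                continue
            if cfg.balance_method == "adasyn":
                X_i, y_i = adasyn_balance(X_i, y_i, cfg.k_neighbors, rng=rng)
            ind_models[aid] = train_classifier(X_i, y_i, cfg)
        for cond in test_conditions:
            for aid in animals:
                te = t[te_mask & (t.condition == cond).to_numpy() & (t.animal_id == aid).to_numpy()]
                if len(te) == 0:
                    rows.append(("population", cond, aid, i, np.nan))
                    continue
                X_te, y_te = make_xy(te, feature_names)
                if len(np.unique(y_te)) < 2:
                    continue
                rows.append(("population", cond, aid, i, evaluate_auc(pop_model, X_te, y_te)))
                if aid in ind_models:
                    rows.append(("individual", cond, aid, i,
                                 evaluate_auc(ind_models[aid], X_te, y_te)))
    return pd.DataFrame(rows, columns=["scheme", "test_condition", "animal_id", "iteration", "auc"])


def learning_curve(
    table: pd.DataFrame,
    feature_names: list[str],
    cfg: EvalConfig,
    bins_grid: list[int],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """AUC vs bins-per-animal, and the plateau point.

    Plateau is the smallest grid value whose AUC distribution is not
    significantly different (two-sample t, Bonferroni across the grid)
    from the distribution at the largest grid value.
    """
    t = table.reset_index(drop=True)
    avail = t.groupby("animal_id").size().min()
    grid = sorted({min(b, int(avail)) for b in bins_grid})
    if max(bins_grid) > avail:
        logger.warning("learning_curve: grid truncated to %d bins per animal", avail)
    rows = []
    for nb in grid:
        for i in range(cfg.n_iterations):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, nb, i]))
            sub = pd.concat(
                [
                    g.sample(n=min(nb, len(g)), random_state=int(rng.integers(2**31)))
                    for _, g in t.groupby("animal_id", sort=True)
                ]
            ).reset_index(drop=True)
            tr_mask, te_mask = split_80_20(sub, rng, cfg.train_fraction)
            X_tr, y_tr = make_xy(sub[tr_mask], feature_names)
            X_te, y_te = make_xy(sub[te_mask], feature_names)
            if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                continue
            rows.append((nb, i, _fit_eval(X_tr, y_tr, X_te, y_te, cfg, rng)))
    df = pd.DataFrame(rows, columns=["bins_per_animal", "iteration", "auc"])
    ref = df[df.bins_per_animal == grid[-1]].auc.to_numpy()
    plateau = grid[-1]
    n_tests = max(1, len(grid) - 1)
    for nb in grid[:-1]:
        s = df[df.bins_per_animal == nb].auc.to_numpy()
        if len(s) < 2:
            continue
        p = stats.ttest_ind(s, ref, equal_var=False).pvalue
        if p > alpha / n_tests:
            plateau = nb
            break
    return df, plateau
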