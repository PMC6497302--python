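"""Within-session classifiers: ADASYN, AUC, repeated eval, designs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpdecode.within_session import (
    EvalConfig,
    GeneralizationDesign,
    adasyn_balance,
    animal_count_sweep,
    evaluate_auc,
    individual_vs_population,
    learning_curve,
    make_xy,
    repeated_eval,
    split_80_20,
    train_classifier,
)

from conftest import small_cohort_config
from lfpdecode.synth import cohort_table, generate_feature_cohort

META = ("bin_start_s", "label", "rest", "lag_s", "animal_id", "condition", "session_id")


def _names(table):
    return [c for c in table.columns if c not in META]


class TestAdasyn:
    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.r_[np.ones(20), np.zeros(20)]
        Xb, yb = adasyn_balance(X, y, rng=rng)
        assert len(yb) == 40

    def test_imbalanced_count_formula(self, rng):
        """Nmaj=900, Nmin=100 -> ~800 synthetic points, final ratio ~1:1."""
        X = np.vstack([rng.standard_normal((900, 4)), 3 + rng.standard_normal((100, 4))])
        y = np.r_[np.zeros(900), np.ones(100)]
        Xb, yb = adasyn_balance(X, y, rng=rng)
        n_min, n_maj = (yb == 1).sum(), (yb == 0).sum()
        assert n_maj == 900
        assert abs(n_min / n_maj - 1.0) < 0.05

    def test_density_weighting_on_toy_set(self):
        """Hand-computed density weights: a minority point whose 2-NN are
        both majority gets r=1; the adjacent pair (one minority, one
        majority neighbor each) get r=0.5 -> normalized weights
        [0.5, 0.25, 0.25], so the isolated point spawns the most."""
        from lfpdecode.within_session import adasyn_weights

        Xmin = np.array([[0.0, 0.0], [10.0, 10.0], [10.5, 10.0]])
        Xmaj = np.array([[0.2, 0.1], [-0.2, 0.1], [0.0, -0.25], [0.1, 0.3],
                         [11.0, 12.0], [12.0, 11.0], [13.0, 13.0]])
        X = np.vstack([Xmin, Xmaj])
        y = np.r_[np.ones(3), np.zeros(7)]
        r = adasyn_weights(X, y, k=2, minority=1.0)
        assert np.allclose(r, [0.5, 0.25, 0.25])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            adasyn_balance(rng.standard_normal((10, 2)), np.ones(10), rng=rng)


class TestAuc:
    def test_worked_example(self):
        """labels [1,1,0,0], scores [.9,.4,.6,.2] -> 3/4 concordant pairs."""
        class M:
            def predict_proba(self, X):
                s = np.array([0.9, 0.4, 0.6, 0.2])
                return np.c_[1 - s, s]

        auc = evaluate_auc(M(), np.zeros((4, 1)), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(0.75)

    def test_perfect_and_tied(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.r_[np.ones(10), np.zeros(10)]

        class Perfect:
            def predict_proba(self, X_):
                s = np.r_[np.linspace(0.6, 0.9, 10), np.linspace(0.1, 0.4, 10)]
                return np.c_[1 - s, s]

        class Flat:
            def predict_proba(self, X_):
                return np.full((len(X_), 2), 0.5)

        assert evaluate_auc(Perfect(), X, y) == 1.0
        assert evaluate_auc(Flat(), X, y) == 0.5

    def test_one_class_test_set_rejected(self, rng):
        class M:
            def predict_proba(self, X_):
                return np.full((len(X_), 2), 0.5)

        with pytest.raises(ValueError):
            evaluate_auc(M(), rng.standard_normal((5, 1)), np.ones(5))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(6, 60))
    def test_auc_equals_pairwise_concordance(self, seed, n):
        """Oracle equivalence: sklearn midrank AUC == brute-force count of
        concordant positive-negative pairs on small test sets."""
        r = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[r.choice(n, max(1, n // 3), replace=False)] = 1
        if y.all() or not y.any():
            return
        scores = np.round(r.random(n), 2)  # ties likely

        class M:
            def predict_proba(self, X_):
                return np.c_[1 - scores, scores]

        auc = evaluate_auc(M(), np.zeros((n, 1)), y)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestTrainClassifier:
    def test_duplicated_feature_prediction_equivalence(self, rng):
        """Duplicating a feature leaves predicted probabilities unchanged
        (coefficients may split between the copies)."""
        X = rng.standard_normal((200, 1))
        y = (X[:, 0] + 0.5 * rng.standard_normal(200) > 0).astype(int)
        cfg = EvalConfig()
        m1 = train_classifier(X, y, cfg)
        m2 = train_classifier(np.c_[X, X], y, cfg)
        p1 = m1.predict_proba(X)[:, 1]
        p2 = m2.predict_proba(np.c_[X, X])[:, 1]
        assert np.abs(p1 - p2).max() < 0.02

    def test_shuffled_labels_test_at_chance(self, rng):
        X = rng.standard_normal((400, 10))
        y = (X[:, 0] > 0).astype(int)
        ys = rng.permutation(y)
        m = train_classifier(X[:300], ys[:300], EvalConfig())
        auc = evaluate_auc(m, X[300:], y[300:])
        assert abs(auc - 0.5) < 0.15


class TestRepeatedEval:
    @pytest.fixture(scope="class")
    def table(self):
        return cohort_table(generate_feature_cohort(small_cohort_config()))

    def test_split_is_disjoint_and_stratified(self, table, rng):
        t = table.reset_index(drop=True)
        tr, te = split_80_20(t, rng)
        assert not (tr & te).any()
        assert tr.sum() + te.sum() == len(t)
        for aid, grp in t.groupby("animal_id"):
            frac = tr[t.animal_id == aid].mean()
            assert 0.7 < frac < 0.9

    def test_planted_effect_beats_permuted(self, table):
        dist = repeated_eval(table, _names(table), EvalConfig(n_iterations=5, seed=3))
        assert dist.mean > dist.null_mean + 0.2

    def test_deterministic_under_seed(self, table):
        cfg = EvalConfig(n_iterations=3, seed=9)
        a = repeated_eval(table, _names(table), cfg)
        b = repeated_eval(table, _names(table), cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.null_samples, b.null_samples)

    def test_permuted_calibration(self, table):
        """Permuted-label pipeline stays within 3 SE of chance."""
        dist = repeated_eval(table, _names(table), EvalConfig(n_iterations=10, seed=4))
        null = dist.null_samples
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.5) < max(3 * se, 0.06)

    def test_individual_scheme_needs_one_animal(self, table):
        with pytest.raises(ValueError):
            repeated_eval(table, _names(table), EvalConfig(n_iterations=1),
                          design=GeneralizationDesign(scheme="individual"))


class TestDesigns:
    @pytest.fixture(scope="class")
    def table(self):
        cfg = small_cohort_config(n_animals=5, session_length_s=900.0, seed=19)
        return cohort_table(generate_feature_cohort(cfg))

    def test_animal_count_sweep_shape(self, table):
        out = animal_count_sweep(table, _names(table), EvalConfig(n_iterations=1, seed=0),
                                 k_values=range(1, 5), max_subsets=4)
        assert set(out.k_train) == {1, 2, 3, 4}

    def test_animal_count_k_out_of_range(self, table):
        with pytest.raises(ValueError):
            animal_count_sweep(table, _names(table), EvalConfig(n_iterations=1),
                               k_values=range(5, 6))

    def test_individual_vs_population_columns(self, table):
        out = individual_vs_population(table, _names(table), EvalConfig(n_iterations=2, seed=1))
        assert {"diff_vs_population", "diff_vs_loo"} <= set(out.columns)
        assert out.animal_id.nunique() >= 4

    def test_learning_curve_plateau_exists(self, table):
        df, plateau = learning_curve(table, _names(table),
                                     EvalConfig(n_iterations=3, seed=2),
                                     bins_grid=[40, 80, 160])
        assert plateau in {40, 80, 160}

    def test_pure_noise_learning_curve_flat(self):
        cfg = small_cohort_config(n_animals=3, session_length_s=900.0,
                                  effect_table={}, condition_effects={}, seed=23)
        t = cohort_table(generate_feature_cohort(cfg))
        df, plateau = learning_curve(t, _names(t), EvalConfig(n_iterations=3, seed=3),
                                     bins_grid=[40, 80, 160])
        assert plateau == 40  # all points at chance


class TestBacktest:
    def test_lag_grid_and_ramp_monotonicity(self):
        """With a 45-s linear ramp the backtest AUC is highest at the
        shortest lag and trends downward across the 9-lag grid."""
        from scipy.stats import spearmanr

        from lfpdecode.within_session import prefeeding_backtest

        cfg = small_cohort_config(n_animals=6, session_length_s=1800.0, seed=29)
        t = cohort_table(generate_feature_cohort(cfg))
        out = prefeeding_backtest(t, _names(t), EvalConfig(n_iterations=5, seed=5))
        mean_by_lag = out.groupby("lag_s").auc.mean().dropna()
        assert len(mean_by_lag) == 9
        assert mean_by_lag.index.max() == 42.5
        rho, _ = spearmanr(mean_by_lag.index, mean_by_lag.values)
        assert rho < -0.5

    def test_no_ramp_means_chance_at_long_lags(self):
        from lfpdecode.within_session import prefeeding_backtest

        cfg = small_cohort_config(n_animals=6, session_length_s=1800.0,
                                  ramp_length_s=0.0, seed=31)
        t = cohort_table(generate_feature_cohort(cfg))
        out = prefeeding_backtest(t, _names(t), EvalConfig(n_iterations=5, seed=6))
        far = out[out.lag_s >= 22.5].auc.dropna()
        assert abs(far.mean() - 0.5) < 0.08
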