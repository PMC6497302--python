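"""Whole-session analysis: rest normalization, lasso CV, nulls, effect size."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lfpdecode.whole_session import (
    CVConfig,
    SessionSummary,
    chewing_artifact_screen,
    deprivation_delta,
    l1_logistic_path,
    lasso_cv_predict,
    mwu_to_cohens_d,
    permutation_null,
    rest_normalize,
)


def _labeled_table(rng, n_feed=30, n_rest=30, shift=0.0, feature="f0", n_features=4):
    rows = []
    for label, rest, n in (("feeding", False, n_feed), ("notfeed", True, n_rest)):
        x = rng.standard_normal((n, n_features))
        df = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
        if label == "feeding" and shift:
            df[feature] += shift
        df["label"] = label
        df["rest"] = rest
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["bin_start_s"] = np.arange(len(out)) * 5.0
    return out


class TestRestNormalize:
    def test_feeding_minus_rest_sign(self, rng):
        t = _labeled_table(rng, shift=2.0)
        names = ["f0", "f1", "f2", "f3"]
        s = rest_normalize(t, names)
        assert s.rest_normalized["f0"] > 1.0  # planted +2 shift
        # unshifted features near zero, within 3 standard errors
        se = np.sqrt(2 / 30)
        for f in names[1:]:
            assert abs(s.rest_normalized[f]) < 3 * se

    def test_identical_states_give_zero(self):
        t = pd.DataFrame(
            {
                "f0": [1.0] * 10,
                "label": ["feeding"] * 5 + ["notfeed"] * 5,
                "rest": [False] * 5 + [True] * 5,
            }
        )
        s = rest_normalize(t, ["f0"])
        assert s.rest_normalized["f0"] == 0.0

    def test_insufficient_rest_bins_rejected(self, rng):
        t = _labeled_table(rng, n_rest=2)
        with pytest.raises(ValueError, match="insufficient"):
            rest_normalize(t, ["f0"])


class TestDeprivationDelta:
    @staticmethod
    def _summary(animal, condition, values):
        s = pd.Series(values)
        return SessionSummary(animal, condition, s, s * 0, s)

    def test_base_minus_dep(self):
        b = self._summary("r1", "Base", {"f0": 2.0})
        d = self._summary("r1", "Dep24", {"f0": 5.0})
        assert deprivation_delta(b, d)["f0"] == -3.0

    def test_antisymmetry_and_zero(self):
        b = self._summary("r1", "Base", {"f0": 2.0, "f1": -1.0})
        d = self._summary("r1", "Dep48", {"f0": 5.0, "f1": -1.0})
        delta = deprivation_delta(b, d)
        assert delta["f1"] == 0.0
        b2 = self._summary("r1", "Base", {"f0": 5.0, "f1": -1.0})
        d2 = self._summary("r1", "Dep48", {"f0": 2.0, "f1": -1.0})
        assert (deprivation_delta(b2, d2) == -delta).all()

    def test_mismatched_animals_rejected(self):
        b = self._summary("r1", "Base", {"f0": 1.0})
        d = self._summary("r2", "Dep24", {"f0": 1.0})
        with pytest.raises(ValueError):
            deprivation_delta(b, d)


class TestLassoCV:
    def test_noiseless_linear_recovery(self, rng):
        X = rng.standard_normal((24, 58))
        y = 2.0 * X[:, 3]
        dist = lasso_cv_predict(X, y, CVConfig(n_iterations=10, seed=0))
        assert dist.metric == "MAE"
        assert dist.mean < 0.1 * y.std()
        assert dist.selection_frequency.iloc[3] > 0.8

    def test_planted_support_recovery(self, rng):
        """Planted support {f3, f17} at high SNR: both survive most CV
        iterations while the median spurious feature rarely does."""
        X = rng.standard_normal((24, 58))
        y = 3.0 * X[:, 3] - 3.0 * X[:, 17] + 0.1 * rng.standard_normal(24)
        dist = lasso_cv_predict(X, y, CVConfig(n_iterations=20, seed=1))
        freq = dist.selection_frequency
        assert freq.iloc[3] > 0.8 and freq.iloc[17] > 0.8
        spurious = freq.drop(freq.index[[3, 17]])
        assert spurious.median() < 0.2

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_cv_predict(rng.standard_normal((10, 3)), np.ones(10))

    def test_mae_invariant_to_column_permutation(self, rng):
        X = rng.standard_normal((20, 10))
        y = X[:, 2] + 0.3 * rng.standard_normal(20)
        a = lasso_cv_predict(X, y, CVConfig(n_iterations=5, seed=3))
        b = lasso_cv_predict(X[:, ::-1], y, CVConfig(n_iterations=5, seed=3))
        assert np.abs(a.samples - b.samples).max() < 1e-3

    def test_selection_frequency_bounded(self, rng):
        X = rng.standard_normal((20, 10))
        y = X[:, 0] + rng.standard_normal(20)
        dist = lasso_cv_predict(X, y, CVConfig(n_iterations=5, seed=4))
        f = dist.selection_frequency
        assert ((f >= 0) & (f <= 1)).all()


class TestPathSolver:
    def test_matches_liblinear(self, rng):
        """Batched FISTA path agrees with sklearn's liblinear L1 logistic
        on coefficients and predictions."""
        from sklearn.linear_model import LogisticRegression

        X = rng.standard_normal((60, 8))
        y = (X[:, 0] - 0.5 * X[:, 1] + 0.8 * rng.standard_normal(60) > 0).astype(float)
        for C in (0.1, 1.0, 10.0):
            W = l1_logistic_path(X, y[:, None], np.array([1.0 / C]), n_iter=3000)
            sk = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=10000, tol=1e-10
            ).fit(X, y)
            assert np.abs(W[1:, 0] - sk.coef_.ravel()).max() < 0.05
            p_ours = 1 / (1 + np.exp(-(W[0, 0] + X @ W[1:, 0])))
            p_sk = sk.predict_proba(X)[:, 1]
            # small systematic offset: liblinear penalizes the intercept
            assert np.abs(p_ours - p_sk).max() < 0.05

    def test_strong_penalty_gives_intercept_only(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.r_[np.ones(18), np.zeros(12)]
        W = l1_logistic_path(X, y[:, None], np.array([1e3]))
        assert np.abs(W[1:, 0]).max() < 1e-8
        assert W[0, 0] == pytest.approx(np.log(18 / 12), abs=1e-3)


class TestPermutationNull:
    def test_null_mae_worse_than_actual_with_signal(self, rng):
        X = rng.standard_normal((24, 20))
        y = 2.0 * X[:, 0] + 0.2 * rng.standard_normal(24)
        cfg = CVConfig(n_iterations=5, seed=5)
        actual = lasso_cv_predict(X, y, cfg)
        null = permutation_null(X, y, cfg, n_perm=5, iterations_per_perm=2)
        assert null.samples.mean() > actual.mean

    def test_binary_null_centered_at_chance(self, rng):
        X = rng.standard_normal((20, 30))
        y = np.r_[np.ones(10), np.zeros(10)]
        null = permutation_null(X, y, CVConfig(n_iterations=5, seed=6),
                                n_perm=20, iterations_per_perm=5)
        assert abs(null.samples.mean() - 0.5) < 0.05

    def test_global_null_calibration(self, rng):
        """With y independent of X, actual and null CV distributions are
        statistically indistinguishable (Mann-Whitney)."""
        hits = 0
        reps = 10
        for r in range(reps):
            rr = np.random.default_rng(r)
            X = rr.standard_normal((24, 15))
            y = rr.standard_normal(24)
            cfg = CVConfig(n_iterations=5, seed=r)
            actual = lasso_cv_predict(X, y, cfg)
            null = permutation_null(X, y, cfg, n_perm=4, iterations_per_perm=3)
            p = stats.mannwhitneyu(actual.samples, null.samples).pvalue
            hits += p > 0.01
        assert hits >= int(0.8 * reps)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_null(rng.standard_normal((10, 3)), rng.standard_normal(10), n_perm=1)


class TestCohensD:
    def test_identical_distributions_near_zero(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        assert abs(mwu_to_cohens_d(a, b)) < 0.35

    def test_unit_shift_recovers_one(self, rng):
        """Normal(0,1) vs Normal(1,1): the U-based conversion agrees with
        the pooled-SD Cohen's d on the same draws."""
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000) + 1.0
        d = mwu_to_cohens_d(b, a)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        direct = (b.mean() - a.mean()) / pooled
        assert d == pytest.approx(direct, abs=0.15)
        assert d == pytest.approx(1.0, abs=0.15)

    def test_complete_separation_is_large(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 100.0
        assert abs(mwu_to_cohens_d(b, a)) > 3.0

    def test_all_tied_returns_zero(self):
        assert mwu_to_cohens_d(np.ones(10), np.ones(10)) == 0.0


class TestChewingScreen:
    @staticmethod
    def _cohort(rng, couple=False):
        summaries, voracity = [], {}
        names = [f"f{i}" for i in range(6)]
        for a in range(8):
            aid = f"rat{a}"
            v_base = 1.5 + 0.2 * rng.standard_normal()
            v_dep = v_base * (1.3 + 0.5 * rng.standard_normal())
            voracity[(aid, "Base")] = v_base
            voracity[(aid, "Dep24")] = v_dep
            for cond, v in (("Base", v_base), ("Dep24", v_dep)):
                vals = pd.Series(1.0 + 0.05 * rng.standard_normal(6), index=names)
                if couple:
                    vals["f0"] = 1.0 + 0.5 * (v - 1.5)  # proportional to voracity
                s = SessionSummary(aid, cond, vals, vals * 0, vals)
                summaries.append(s)
        return summaries, voracity, names

    def test_planted_confound_flagged(self, rng):
        summaries, voracity, names = self._cohort(rng, couple=True)
        out = chewing_artifact_screen(summaries, voracity, names)
        row = out[out.feature == "f0"].iloc[0]
        assert row.flagged
        assert row.r2 > 0.25

    def test_type_one_error_calibrated(self):
        """Independent features are flagged in <~5% of null screens at
        p < 0.01 (binomial tolerance over 200 screens)."""
        flags = total = 0
        for r in range(200):
            rng = np.random.default_rng(1000 + r)
            summaries, voracity, names = self._cohort(rng, couple=False)
            out = chewing_artifact_screen(summaries, voracity, names)
            flags += int(out.flagged.sum())
            total += len(out)
        assert flags / total < 0.05

    def test_constant_voracity_skips_screen(self, rng):
        summaries, voracity, names = self._cohort(rng)
        voracity = {k: 2.0 for k in voracity}
        out = chewing_artifact_screen(summaries, voracity, names)
        assert out.empty
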