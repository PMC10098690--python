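"""Ranker behavior: planted-signal recovery, invariances, top-k selection."""

import numpy as np
import pandas as pd
import pytest

from thermaffect import rank_anova, rank_nb, rank_nca, rank_pca, select_top
from thermaffect.core import ValidationError
from thermaffect.features import FeatureTable
from thermaffect.selection import DEFAULT_K, RankingResult


def two_class_data(rng, n=50, p=10):
    X = rng.standard_normal((2 * n, p))
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestRankAnova:
    def test_identical_feature_ranked_last(self, rng):
        X, y = two_class_data(rng)
        X[:, 4] = 1.0  # no variance at all -> F = 0
        r = rank_anova(X, y)
        assert r.scores[4] == 0.0
        assert r.order[-1] == 4 or r.scores[r.order[-1]] == 0.0

    def test_strong_mean_shift_ranks_first(self, rng):
        """Means 0 vs 10 with unit SD: textbook F ~ n * 25 dominates noise."""
        X, y = two_class_data(rng, n=50, p=20)
        X[:50, 7] += 10.0
        r = rank_anova(X, y)
        assert r.order[0] == 7
        # cross-check F against the textbook two-group formula
        a, b = X[:50, 7], X[50:, 7]
        na, nb = len(a), len(b)
        gm = X[:, 7].mean()
        ssb = na * (a.mean() - gm) ** 2 + nb * (b.mean() - gm) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_manual = (ssb / 1) / (ssw / (na + nb - 2))
        assert r.scores[7] == pytest.approx(f_manual, rel=1e-10)

    def test_scale_invariance_of_ranking(self, rng):
        X, y = two_class_data(rng, p=8)
        X[:50, 2] += 1.5
        r1 = rank_anova(X, y)
        scales = rng.uniform(0.1, 10, X.shape[1])
        r2 = rank_anova(X * scales, y)
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValidationError):
            rank_anova(X, np.array(["a"] * 10))


class TestRankPca:
    def test_perfectly_correlated_features_score_equally(self, rng):
        X = rng.standard_normal((60, 5))
        X[:, 3] = X[:, 1]
        r = rank_pca(X)
        assert r.scores[1] == pytest.approx(r.scores[3], rel=1e-9)

    def test_dominant_structured_feature_ranks_first(self, rng):
        """A latent signal shared weakly by all features but carried almost
        noise-free by one of them: that feature dominates the top component."""
        X = rng.normal(0, 1.0, (80, 10))
        t = rng.standard_normal(80)
        X += 0.5 * t[:, None]  # weak shared structure -> defines PC1
        X[:, 6] = t + rng.normal(0, 0.05, 80)  # near-pure copy of the signal
        r = rank_pca(X)
        assert r.order[0] == 6

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((40, 6))
        r1 = rank_pca(X)
        perm = rng.permutation(40)
        r2 = rank_pca(X[perm])
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-9)

    def test_constant_column_scored_zero(self, rng):
        X = rng.standard_normal((30, 4))
        X[:, 2] = 3.0
        r = rank_pca(X)
        assert r.scores[2] == 0.0
        assert r.order[-1] == 2


class TestRankNca:
    def test_informative_feature_first_across_seeds(self):
        """One separating feature among 20 noise features, 50 seeded runs."""
        wins = 0
        for s in range(50):
            rng = np.random.default_rng(4000 + s)
            X = rng.standard_normal((60, 21))
            y = np.array(["a"] * 30 + ["b"] * 30)
            X[:30, 0] += 3.0
            r = rank_nca(X, y, seed=s)
            wins += int(r.order[0] == 0)
        assert wins >= 48  # >= 95% of runs

    def test_duplicated_informative_feature_both_top3(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 20))
        y = np.array(["a"] * 40 + ["b"] * 40)
        X[:40, 4] += 2.5
        X[:, 9] = X[:, 4]
        r = rank_nca(X, y, seed=0)
        assert {4, 9} <= set(r.order[:3])

    def test_pure_noise_shows_no_systematic_bias(self):
        """Top-1 index is spread across features, never stuck on one."""
        tops = []
        for s in range(30):
            rng = np.random.default_rng(7000 + s)
            X = rng.standard_normal((40, 12))
            y = np.array(["a"] * 20 + ["b"] * 20)
            tops.append(rank_nca(X, y, seed=s).order[0])
        assert len(set(tops)) >= 5

    def test_result_is_valid_permutation_and_flags_convergence(self, rng):
        X, y = two_class_data(rng, n=20, p=6)
        r = rank_nca(X, y, seed=0, max_iter=2)
        assert sorted(r.order.tolist()) == list(range(6))
        assert isinstance(r.converged, bool)


class TestRankNb:
    def test_perfect_separator_scores_one(self, rng):
        X, y = two_class_data(rng, n=25, p=5)
        X[:25, 2] = 10.0 + 0.01 * rng.standard_normal(25)
        X[25:, 2] = -10.0 + 0.01 * rng.standard_normal(25)
        r = rank_nb(X, y, seed=0)
        assert r.order[0] == 2
        assert r.scores[2] == 1.0

    def test_noise_feature_near_chance(self):
        scores = []
        for s in range(10):
            rng = np.random.default_rng(800 + s)
            X = rng.standard_normal((100, 1))
            y = np.array(["a"] * 50 + ["b"] * 50)
            scores.append(rank_nb(X, y, seed=s).scores[0])
        assert 0.35 < float(np.mean(scores)) < 0.65

    def test_scorer_is_per_feature_independent(self, rng):
        X, y = two_class_data(rng, n=30, p=4)
        r1 = rank_nb(X, y, seed=3)
        X2 = np.hstack([X, rng.standard_normal((60, 1))])
        r2 = rank_nb(X2, y, seed=3)
        np.testing.assert_allclose(r1.scores, r2.scores[:4], atol=1e-12)

    def test_matches_sklearn_gaussian_nb(self, rng):
        """Dual route: the vectorized scorer equals per-feature GaussianNB."""
        from sklearn.model_selection import StratifiedKFold
        from sklearn.naive_bayes import GaussianNB

        X, y = two_class_data(rng, n=30, p=6)
        X[:30, 1] += 1.0
        r = rank_nb(X, y, n_folds=5, seed=11, var_floor=1e-9)
        classes, codes = np.unique(y, return_inverse=True)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=11)
        for j in range(6):
            correct, total = 0, 0
            for tr, te in skf.split(X, codes):
                clf = GaussianNB(var_smoothing=0.0)
                clf.fit(X[tr, j : j + 1], codes[tr])
                correct += int((clf.predict(X[te, j : j + 1]) == codes[te]).sum())
                total += len(te)
            assert r.scores[j] == pytest.approx(correct / total, abs=1e-12)


class TestSelectTop:
    def make_table(self, rng, p=12):
        df = pd.DataFrame(rng.standard_normal((20, p)),
                          columns=[f"c{i}" for i in range(p)],
                          index=[f"s{i}" for i in range(20)])
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index)
        return FeatureTable(df, labels, "main6")

    def test_full_width_is_column_reordering(self, rng):
        table = self.make_table(rng)
        r = rank_anova(table.X, table.y, k=12)
        out = select_top(r, table, k=12)
        assert sorted(out.data.columns) == sorted(table.data.columns)

    def test_default_depths(self, rng):
        X = rng.standard_normal((30, 60))
        y = np.array(["a"] * 15 + ["b"] * 15)
        assert rank_anova(X, y).k_selected == 50
        assert rank_pca(X).k_selected == 50
        assert rank_nb(X, y).k_selected == 10
        r = rank_nca(X, y, seed=0, max_iter=5)
        assert r.k_selected == 10
        assert select_top(r, X).shape == (30, 10)

    def test_k_beyond_width_rejected(self, rng):
        table = self.make_table(rng, p=5)
        r = rank_anova(table.X, table.y, k=5)
        with pytest.raises(ValidationError):
            select_top(r, table, k=6)

    def test_idempotent_on_arrays(self, rng):
        X, y = two_class_data(rng, n=10, p=8)
        r = rank_anova(X, y, k=4)
        once = select_top(r, X)
        assert once.shape == (20, 4)
        np.testing.assert_array_equal(once, X[:, r.order[:4]])


class TestPlantedSignalRecovery:
    """Five informative features among 95 noise: every ranker finds >= 4
    within its selection depth in >= 90% of replicates."""

    def test_all_rankers_recover_planted_features(self):
        informative = [3, 17, 41, 62, 88]
        hits = {"pca": 0, "anova": 0, "nca": 0, "nb": 0}
        n_rep = 10
        for s in range(n_rep):
            rng = np.random.default_rng(9100 + s)
            X = rng.standard_normal((120, 100))
            y = np.array(["a"] * 60 + ["b"] * 60)
            for j in informative:
                X[:60, j] += 2.0
            results = {
                "pca": rank_pca(X, k=50),
                "anova": rank_anova(X, y, k=50),
                "nca": rank_nca(X, y, seed=s, k=10),
                "nb": rank_nb(X, y, seed=s, k=10),
            }
            for name, r in results.items():
                found = len(set(informative) & set(r.order[: r.k_selected]))
                hits[name] += int(found >= 4)
        for name, h in hits.items():
            assert h >= 0.9 * n_rep, f"{name}: {h}/{n_rep}"
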