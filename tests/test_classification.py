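"""One-vs-one protocol: task construction, metrics, kappa, aggregation."""

import numpy as np
import pandas as pd
import pytest

from thermaffect import (
    ClassifierSpec,
    aggregate,
    cohens_kappa,
    make_binary_tasks,
    run_task,
)
from thermaffect.core import EMOTIONS, ValidationError
from thermaffect.features import FeatureTable


def synthetic_table(rng, counts, p=12, separation=0.0):
    """Feature table with optional per-class mean separation."""
    classes = list(counts)
    rows, labels = [], []
    for ci, (cls, n) in enumerate(counts.items()):
        block = rng.standard_normal((n, p))
        if separation:
            block[:, ci % p] += separation * (ci + 1)
        rows.append(block)
        labels += [cls] * n
    X = np.vstack(rows)
    idx = [f"s{i}" for i in range(len(X))]
    df = pd.DataFrame(X, columns=[f"c{i}" for i in range(p)], index=idx)
    return FeatureTable(df, pd.Series(labels, index=idx), "main6")


class TestMakeBinaryTasks:
    def test_six_classes_give_15_tasks(self, rng):
        table = synthetic_table(rng, {e: 20 for e in EMOTIONS})
        tasks = make_binary_tasks(table, seed=0)
        assert len(tasks) == 15
        assert len({t.class_pair for t in tasks}) == 15

    def test_downsampling_to_minority_size(self, rng):
        table = synthetic_table(rng, {"happy": 99, "fear": 55})
        (task,) = make_binary_tasks(table, seed=0)
        assert len(task.y) == 110
        assert (task.y == "happy").sum() == 55
        assert (task.y == "fear").sum() == 55

    def test_two_classes_give_one_task(self, rng):
        table = synthetic_table(rng, {"anger": 30, "sad": 30})
        tasks = make_binary_tasks(table, seed=1)
        assert len(tasks) == 1

    def test_folds_partition_rows(self, rng):
        table = synthetic_table(rng, {"anger": 25, "sad": 25})
        (task,) = make_binary_tasks(table, seed=2)
        assert len(task.folds) == 10
        all_test = np.sort(np.concatenate([te for _, te in task.folds]))
        np.testing.assert_array_equal(all_test, np.arange(len(task.y)))

    def test_small_class_rejected(self, rng):
        table = synthetic_table(rng, {"anger": 8, "sad": 30})
        with pytest.raises(ValidationError):
            make_binary_tasks(table, seed=0)

    def test_deterministic_under_seed(self, rng):
        table = synthetic_table(rng, {"happy": 40, "sad": 25})
        t1 = make_binary_tasks(table, seed=5)[0]
        t2 = make_binary_tasks(table, seed=5)[0]
        np.testing.assert_array_equal(t1.row_ids, t2.row_ids)
        np.testing.assert_array_equal(t1.folds[3][0], t2.folds[3][0])


class TestCohensKappa:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            ([[50, 0], [0, 50]], 1.0),
            ([[25, 25], [25, 25]], 0.0),
            ([[40, 10], [5, 45]], 0.70),
        ],
    )
    def test_known_values(self, cm, expected):
        assert cohens_kappa(np.array(cm)) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_table_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa(np.array([[10, 0], [0, 0]])) == 0.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            y1 = rng.integers(0, 2, 60)
            y2 = rng.integers(0, 2, 60)
            cm = np.zeros((2, 2))
            for a, b in zip(y1, y2):
                cm[a, b] += 1
            if cm.sum(axis=0).min() == 0 or cm.sum(axis=1).min() == 0:
                continue
            assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)


class TestRunTask:
    def test_separable_pair_perfect_metrics(self, rng):
        table = synthetic_table(rng, {"happy": 30, "sad": 30}, separation=8.0)
        (task,) = make_binary_tasks(table, seed=0)
        res = run_task(task, ClassifierSpec("svm"), "anova", k=5, seed=0)
        assert res.mean("accuracy") == 1.0
        assert res.mean("kappa") == 1.0

    def test_mlp_learns_separable_pair(self, rng):
        table = synthetic_table(rng, {"happy": 30, "sad": 30}, separation=8.0)
        (task,) = make_binary_tasks(table, seed=0)
        res = run_task(task, ClassifierSpec("mlp"), "nb", k=5, seed=0)
        assert res.mean("accuracy") >= 0.95

    def test_determinism(self, rng):
        table = synthetic_table(rng, {"fear": 25, "sad": 25}, separation=1.0)
        (task,) = make_binary_tasks(table, seed=3)
        r1 = run_task(task, ClassifierSpec("svm"), "nb", seed=9)
        r2 = run_task(task, ClassifierSpec("svm"), "nb", seed=9)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)

    def test_global_selection_mode_runs(self, rng):
        table = synthetic_table(rng, {"fear": 20, "sad": 20}, separation=2.0)
        (task,) = make_binary_tasks(table, seed=3)
        res = run_task(task, ClassifierSpec("svm"), "anova", k=4, seed=1, global_selection=True)
        assert 0.5 <= res.mean("accuracy") <= 1.0

    def test_unknown_selector_rejected(self, rng):
        table = synthetic_table(rng, {"fear": 20, "sad": 20})
        (task,) = make_binary_tasks(table, seed=0)
        with pytest.raises(ValidationError):
            run_task(task, ClassifierSpec("svm"), "relief")


class TestAggregate:
    def _fake_result(self, pair, acc):
        from thermaffect.classification import TaskResult

        fm = pd.DataFrame(
            {
                "accuracy": [acc],
                "kappa": [2 * acc - 1],
                **{f"{m}_{c}": [acc] for c in pair for m in ("precision", "recall", "f1")},
            }
        )
        return TaskResult(pair, fm, np.eye(2), "nb", 10, {})

    def test_hand_built_class_mean(self):
        import itertools

        classes = ["A", "B", "C", "D", "E", "F"]
        accs = {}
        results = []
        for pair in itertools.combinations(classes, 2):
            acc = {"AB": 0.8, "AC": 0.9, "AD": 1.0, "AE": 0.7, "AF": 0.6}.get(
                "".join(pair), 0.5
            )
            accs[pair] = acc
            results.append(self._fake_result(pair, acc))
        rep = aggregate(results)
        assert rep.per_class.loc["A", "accuracy"] == pytest.approx(0.8)
        a_free = [a for p, a in accs.items() if "A" not in p]
        expected_overall = np.mean(
            [np.mean([a for p, a in accs.items() if c in p]) for c in classes]
        )
        assert rep.overall["accuracy"] == pytest.approx(expected_overall)

    def test_all_perfect_gives_ones(self):
        import itertools

        results = [self._fake_result(p, 1.0) for p in itertools.combinations("ABCDEF", 2)]
        rep = aggregate(results)
        assert (rep.per_class["accuracy"] == 1.0).all()
        assert rep.overall["accuracy"] == 1.0

    def test_overall_invariant_to_task_order(self, rng):
        import itertools

        pairs = list(itertools.combinations("ABCDEF", 2))
        accs = rng.uniform(0.5, 1.0, 15)
        results = [self._fake_result(p, a) for p, a in zip(pairs, accs)]
        rep1 = aggregate(results)
        rep2 = aggregate(results[::-1])
        assert rep1.overall["accuracy"] == pytest.approx(rep2.overall["accuracy"])

    def test_missing_task_refused(self):
        import itertools

        results = [self._fake_result(p, 0.9) for p in itertools.combinations("ABCDEF", 2)][:-1]
        with pytest.raises(ValidationError):
            aggregate(results)


class TestNullCalibrationSmall:
    def test_permuted_labels_near_chance(self, rng):
        """Shuffled labels: pairwise accuracy ~0.5, kappa ~0 (small version)."""
        accs, kappas = [], []
        for s in range(5):
            r = np.random.default_rng(300 + s)
            table = synthetic_table(r, {"a": 40, "b": 40}, p=10)
            perm = r.permutation(len(table.labels))
            table = FeatureTable(
                table.data,
                pd.Series(table.labels.values[perm], index=table.data.index),
                "main6",
            )
            (task,) = make_binary_tasks(table, seed=s)
            res = run_task(task, ClassifierSpec("svm"), "anova", k=5, seed=s)
            accs.append(res.mean("accuracy"))
            kappas.append(res.mean("kappa"))
        assert 0.35 <= float(np.mean(accs)) <= 0.65
        assert -0.25 <= float(np.mean(kappas)) <= 0.25
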