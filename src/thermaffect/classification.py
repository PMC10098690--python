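"""One-against-one classification of the six emotions, with evaluation.

Six classes give C(6,2) = 15 binary tasks. Each task is balanced by random
downsampling of the majority class to the minority size, then split into a
seeded stratified 10-fold partition. Per fold, features are z-scored with
training-fold statistics, a ranker is fit on the training rows only (no
selection leakage; a ``global_selection`` flag instead fits selection once on the
whole task), the top-k columns are kept, a classifier (RBF-SVM or
backpropagation MLP) is trained and the held-out fold is scored.

Reported metrics per task: accuracy, precision/recall/F1 for each class of
the pair, and Cohen's kappa. Aggregation gives one number per class: a
class's accuracy is the mean over its 5 pairwise tasks, and the overall
accuracy the mean of the 6 class means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import ThermaffectError, ValidationError, spawn_seed
from .features import FeatureTable
from .selection import DEFAULT_K, RANKERS, RankingResult

N_FOLDS = 10


@dataclass(frozen=True)
class ClassifierSpec:
    """Serializable classifier configuration.

    SVM: RBF kernel with optimizer stopping tolerance ("epsilon" in some
    toolkits) 0.001, C = 1, gamma = 'scale'. MLP: stochastic backpropagation with
    learning rate 0.01, 500 epochs, momentum 0.2 and 6 hidden layers
    (default width 32; ``narrow=True`` switches to the alternative reading
    of a single 6-unit hidden layer).
    """

    family: str = "svm"
    c: float = 1.0
    gamma: str | float = "scale"
    tol: float = 1e-3
    hidden_width: int = 32
    n_hidden_layers: int = 6
    learning_rate: float = 0.01
    momentum: float = 0.2
    epochs: int = 500
    narrow: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("svm", "mlp"):
            raise ValidationError(f"unknown classifier family {self.family!r}")

    def build(self, seed: int):
        if self.family == "svm":
            return SVC(kernel="rbf", C=self.c, gamma=self.gamma, tol=self.tol,
                       random_state=seed)
        hidden = (6,) if self.narrow else (self.hidden_width,) * self.n_hidden_layers
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            solver="sgd",
            learning_rate_init=self.learning_rate,
            momentum=self.momentum,
            nesterovs_momentum=False,
            max_iter=self.epochs,
            random_state=seed,
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BinaryTask:
    """One balanced class pair with its stratified fold assignment."""

    class_pair: tuple[str, str]
    X: np.ndarray
    y: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    row_ids: np.ndarray

    def __post_init__(self) -> None:
        a, b = self.class_pair
        if int((self.y == a).sum()) != int((self.y == b).sum()):
            raise ValidationError(f"task {self.class_pair} is not balanced")


def make_binary_tasks(
    table: FeatureTable, seed: int = 0, n_folds: int = N_FOLDS
) -> list[BinaryTask]:
    """All unordered class pairs, downsampled to balance, 10-fold stratified."""
    classes = sorted(pd.unique(table.labels))
    counts = table.labels.value_counts()
    short = [c for c in classes if counts[c] < n_folds]
    if short:
        raise ValidationError(
            f"classes {short} have fewer than {n_folds} instances; cannot form folds"
        )
    X, y = table.X, table.y
    ids = np.asarray(table.data.index)
    tasks = []
    for t, (a, b) in enumerate(itertools.combinations(classes, 2)):
        rng = np.random.default_rng(spawn_seed(seed, t))
        ia = np.flatnonzero(y == a)
        ib = np.flatnonzero(y == b)
        m = min(len(ia), len(ib))
        ia = rng.choice(ia, size=m, replace=False)
        ib = rng.choice(ib, size=m, replace=False)
        rows = np.sort(np.concatenate([ia, ib]))
        Xt, yt = X[rows], y[rows]
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spawn_seed(seed, t, 1))
        folds = [(tr, te) for tr, te in skf.split(Xt, yt)]
        tasks.append(BinaryTask((a, b), Xt, yt, folds, ids[rows]))
    return tasks


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``confusion[i, j]`` counts true class i predicted as class j. If the
    expected agreement p_e is 1 (all mass in one row and one column), kappa
    is defined as 0 with a warning.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValidationError("empty confusion matrix")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        warnings.warn("degenerate confusion matrix (p_e = 1); kappa defined as 0")
        return 0.0
    return float((po - pe) / (1.0 - pe))


def _binary_metrics(y_true, y_pred, classes: tuple[str, str]) -> dict:
    a, b = classes
    cm = np.zeros((2, 2))
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            cm[i, j] = np.sum((y_true == ci) & (y_pred == cj))
    out = {"accuracy": float(np.trace(cm) / cm.sum()), "kappa": cohens_kappa(cm)}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[1 - i, i]
        fn = cm[i, 1 - i]
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        out[f"precision_{c}"] = float(prec)
        out[f"recall_{c}"] = float(rec)
        out[f"f1_{c}"] = float(f1)
    out["confusion"] = cm
    return out


@dataclass
class TaskResult:
    """Per-fold and mean metrics of one binary task."""

    class_pair: tuple[str, str]
    fold_metrics: pd.DataFrame
    confusion: np.ndarray
    selector: str
    k: int
    classifier: dict

    def mean(self, metric: str) -> float:
        return float(self.fold_metrics[metric].mean())


def _standardize_fold(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def run_task(
    task: BinaryTask,
    spec: ClassifierSpec = ClassifierSpec(),
    selection_method: str = "nca",
    k: int | None = None,
    seed: int = 0,
    global_selection: bool = False,
    rankings: Sequence[RankingResult] | None = None,
) -> TaskResult:
    """Cross-validate one binary task with fold-internal feature selection.

    ``rankings`` may carry precomputed per-fold rankings (one per fold, e.g.
    shared across classifier families); otherwise the ranker named by
    ``selection_method`` is fit on each training fold. With ``global_selection``
    the ranker is fit once on the full task data before cross-validation,
    mimicking selection outside the CV loop.
    """
    method = selection_method.lower()
    if method not in RANKERS:
        raise ValidationError(f"unknown selection method {selection_method!r}")
    k = k or min(DEFAULT_K[method.upper()], task.X.shape[1])
    full_ranking = None
    if global_selection and rankings is None:
        Z_all, _ = _standardize_fold(task.X, task.X)
        full_ranking = RANKERS[method](Z_all, task.y, spawn_seed(seed, 999))

    rows = []
    confusion = np.zeros((2, 2))
    for fi, (tr, te) in enumerate(task.folds):
        Xtr, Xte = _standardize_fold(task.X[tr], task.X[te])
        ytr, yte = task.y[tr], task.y[te]
        if len(np.unique(ytr)) < 2:
            raise ThermaffectError("training fold contains a single class")
        if rankings is not None:
            ranking = rankings[fi]
        elif global_selection:
            ranking = full_ranking
        else:
            ranking = RANKERS[method](Xtr, ytr, spawn_seed(seed, fi))
        cols = ranking.order[:k]
        clf = spec.build(spawn_seed(seed, fi, 7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr[:, cols], ytr)
            pred = clf.predict(Xte[:, cols])
        m = _binary_metrics(yte, pred, task.class_pair)
        confusion += m.pop("confusion")
        m["fold"] = fi
        rows.append(m)
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    return TaskResult(
        class_pair=task.class_pair,
        fold_metrics=fold_metrics,
        confusion=confusion,
        selector=method,
        k=k,
        classifier=spec.to_dict(),
    )


def compute_fold_rankings(
    task: BinaryTask, selection_method: str, seed: int = 0
) -> list[RankingResult]:
    """Per-fold training-rows rankings, reusable across classifier families."""
    method = selection_method.lower()
    out = []
    for fi, (tr, _) in enumerate(task.folds):
        Xtr, _ = _standardize_fold(task.X[tr], task.X[tr])
        out.append(RANKERS[method](Xtr, task.y[tr], spawn_seed(seed, fi)))
    return out


@dataclass
class EvaluationReport:
    """Per-class and overall means over the 15 one-vs-one tasks."""

    per_task: pd.DataFrame
    per_class: pd.DataFrame
    overall: dict
    classes: tuple[str, ...]

    def summary_row(self) -> dict:
        row = {c: self.per_class.loc[c, "accuracy"] for c in self.classes}
        row["mean"] = self.overall["accuracy"]
        return row


def aggregate(task_results: Sequence[TaskResult]) -> EvaluationReport:
    """Class mean = mean of the class's 5 task accuracies; overall = mean of class means."""
    classes = sorted({c for r in task_results for c in r.class_pair})
    expected = len(classes) * (len(classes) - 1) // 2
    pairs = {r.class_pair for r in task_results}
    if len(task_results) != expected or len(pairs) != expected:
        raise ValidationError(
            f"aggregation needs all {expected} unique pairwise tasks, got {len(task_results)}"
        )
    task_rows = []
    for r in task_results:
        task_rows.append(
            {
                "pair": "-".join(r.class_pair),
                "accuracy": r.mean("accuracy"),
                "kappa": r.mean("kappa"),
                **{
                    f"{m}_{c}": r.mean(f"{m}_{c}")
                    for c in r.class_pair
                    for m in ("precision", "recall", "f1")
                },
            }
        )
    per_task = pd.DataFrame(task_rows).set_index("pair")

    rows = {}
    for c in classes:
        mine = [r for r in task_results if c in r.class_pair]
        rows[c] = {
            "accuracy": float(np.mean([r.mean("accuracy") for r in mine])),
            "precision": float(np.mean([r.mean(f"precision_{c}") for r in mine])),
            "recall": float(np.mean([r.mean(f"recall_{c}") for r in mine])),
            "f1": float(np.mean([r.mean(f"f1_{c}") for r in mine])),
            "kappa": float(np.mean([r.mean("kappa") for r in mine])),
        }
    per_class = pd.DataFrame(rows).T
    overall = {m: float(per_class[m].mean()) for m in per_class.columns}
    return EvaluationReport(per_task, per_class, overall, tuple(classes))


def pairwise_vote(votes: Mapping[tuple[str, str], str]) -> str:
    """Majority vote over pairwise predictions; ties broken alphabetically."""
    tally: dict[str, int] = {}
    for (_, _), winner in votes.items():
        tally[winner] = tally.get(winner, 0) + 1
    best = max(tally.values())
    return sorted(c for c, v in tally.items() if v == best)[0]
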