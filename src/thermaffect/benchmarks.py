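"""Reference study-condition benchmarks.

These functions run the pipeline under its standing conditions (default
cohort sizes, jitter 0.1 degC, sensor noise 0.05 degC, small head motion)
and measure the quantities the package is validated on: transform-recovery
error, null (label-permuted) calibration, and signal recovery with and
without occlusion. They are used by the test suite and by the acceptance
script, and are part of the public API so users can reproduce the numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd

from .classification import ClassifierSpec, aggregate, make_binary_tasks, run_task
from .core import EMOTIONS, spawn_seed
from .features import FeatureTable, build_feature_table, compute_features, remove_outliers
from .layout import ROIPatch, build_layout
from .pipeline import evaluate_cell, feature_tables, preprocess_cohort
from .preprocessing import register_pair
from .synthetic import (
    ALL_OCCLUSIONS,
    CohortConfig,
    FacePhantom,
    MotionSpec,
    default_signatures,
    generate_cohort,
    generate_pair,
)


def feature_oracle_error(n_patches: int = 1000, seed: int = 0) -> float:
    """Max relative error of the nine features vs direct elementwise math.

    The oracle recomputes each statistic from sorted Python lists and plain
    sums, independently of the vectorized implementation.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_patches):
        shape = (int(rng.integers(2, 10)), int(rng.integers(2, 10)))
        apex = rng.normal(34, 2, shape)
        onset = apex - rng.normal(0, 0.5, shape)
        got = compute_features(ROIPatch("p", apex, onset, (0, 0, 0, 0)))
        want = _oracle_features(apex.tolist(), onset.tolist())
        for g, w in zip(got, want):
            err = abs(g - w) / max(1.0, abs(w))
            worst = max(worst, err)
    return worst


def _oracle_features(apex, onset):
    vals = sorted(v for row in apex for v in row)
    diffs = sorted(a - o for ra, ro in zip(apex, onset) for a, o in zip(ra, ro))

    def mean(xs):
        return sum(xs) / len(xs)

    def var(xs):
        m = mean(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    def median(xs):
        k = len(xs) // 2
        return xs[k] if len(xs) % 2 else (xs[k - 1] + xs[k]) / 2.0

    f5, f6 = vals[-1], vals[0]
    return [mean(vals), mean(diffs), var(vals), var(diffs), f5, f6,
            (f5 + f6) / 2.0, median(vals), median(diffs)]


def registration_recovery_grid(seed: int = 0) -> dict[str, float]:
    """Median absolute parameter errors over a 27-point motion grid.

    Rotations {-10, 0, 10} deg x scales {0.95, 1, 1.05} x shifts {-8, 0, 8}
    px (dy = -dx/2), each with sensor noise, recovered by intensity-based
    registration and compared against the generating motion.
    """
    phantom = FacePhantom()
    sigs = default_signatures(0.1)
    errs = []
    for i, (rot, sc, sh) in enumerate(
        itertools.product((-10.0, 0.0, 10.0), (0.95, 1.0, 1.05), (-8.0, 0.0, 8.0))
    ):
        motion = MotionSpec(rotation=rot, scale=sc, translation=(sh, -sh / 2))
        pair, _ = generate_pair(
            phantom, sigs["happy"], motion=motion, noise_sd=0.05,
            seed=spawn_seed(seed, i),
        )
        _, tf, _ = register_pair(pair.onset, pair.apex, residual_threshold=np.inf)
        errs.append(
            (
                abs(tf.rotation - rot),
                abs(tf.scale - sc),
                max(abs(tf.translation[0] - sh), abs(tf.translation[1] + sh / 2)),
            )
        )
    med = np.median(np.asarray(errs), axis=0)
    return {
        "rotation_deg": float(med[0]),
        "scale": float(med[1]),
        "shift_px": float(med[2]),
    }


def null_calibration(
    seed: int = 0, n_seeds: int = 20, n_per_class: int = 100
) -> dict[str, float]:
    """Label-permutation null of the one-vs-one protocol.

    One cohort (identity motion, so the onset frame needs no resampling) is
    generated once; across ``n_seeds`` replicates the emotion labels are
    randomly permuted and the 15 balanced tasks are cross-validated with
    ANOVA selection and the RBF-SVM. Returns the mean pairwise accuracy and
    mean kappa over replicates — both should sit at chance.
    """
    config = CohortConfig(
        n_per_class={e: n_per_class for e in EMOTIONS},
        motion_rotation_max=0.0,
        motion_scale_max=0.0,
        motion_shift_max=0.0,
    )
    records, _ = generate_cohort(config, seed=spawn_seed(seed, 0))
    processed = preprocess_cohort(records, register=False)
    table = build_feature_table(processed, build_layout("main6"))
    accs, kappas = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(spawn_seed(seed, 1, s))
        perm = rng.permutation(len(table.labels))
        shuffled = FeatureTable(
            table.data,
            pd.Series(table.labels.values[perm], index=table.data.index),
            table.layout_id,
        )
        tasks = make_binary_tasks(shuffled, seed=spawn_seed(seed, 2, s))
        results = [
            run_task(t, ClassifierSpec("svm"), "anova", seed=spawn_seed(seed, 3, s, i))
            for i, t in enumerate(tasks)
        ]
        accs.append(float(np.mean([r.mean("accuracy") for r in results])))
        kappas.append(float(np.mean([r.mean("kappa") for r in results])))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "mean_kappa": float(np.mean(kappas)),
        "n_seeds": n_seeds,
        "n_rows": int(len(table.data)),
    }


def signal_recovery(
    seed: int = 0,
    occluded: bool = False,
    models: tuple[str, ...] = ("main6", "sub27", "sel11"),
    selectors: tuple[str, ...] = ("nca", "nb"),
) -> dict[str, float]:
    """Overall mean accuracy per (model, selector) on the default cohort.

    The full pipeline runs: generation (with eyeglass + beard + mustache +
    bangs occlusion if requested), face extraction, onset-to-apex
    registration, ROI cropping, feature extraction, class-wise 3-SD outlier
    filtering, fold-internal selection and RBF-SVM one-vs-one evaluation.
    """
    occ = ALL_OCCLUSIONS if occluded else None
    config = CohortConfig(occlusion=occ) if occ else CohortConfig()
    records, _ = generate_cohort(config, seed=spawn_seed(seed, 10))
    processed = preprocess_cohort(records, register=True)
    tables = feature_tables(processed, models, outlier_filter=True)
    out = {"n_pairs": len(records), "n_processed": len(processed)}
    for model in models:
        for selector in selectors:
            rep = evaluate_cell(
                tables[model], selector, "svm", seed=spawn_seed(seed, 11)
            )
            out[f"{model}_{selector}"] = float(rep.overall["accuracy"])
    return out
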