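"""End-to-end orchestration: simulate -> preprocess -> ROIs -> features ->
select -> classify -> report, under a single config and master seed.

A completed run directory contains the config copy, package/library
versions, the seeds used, per-model feature tables, per-cell evaluation
reports (JSON), a summary accuracy matrix per model (one row per
classifier x selector combination, one column per class plus the overall
mean) and a model-comparison figure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classification import (
    ClassifierSpec,
    EvaluationReport,
    aggregate,
    compute_fold_rankings,
    make_binary_tasks,
    run_task,
)
from .core import EMOTIONS, ThermaffectError, ValidationError, spawn_seed
from .features import FeatureTable, build_feature_table, remove_outliers
from .layout import MODEL_IDS, build_layout
from .preprocessing import extract_face, register_pair
from .selection import DEFAULT_K, RANKERS
from .synthetic import CohortConfig, CohortRecord, OcclusionSpec, generate_cohort

logger = logging.getLogger(__name__)

SELECTORS = ("pca", "anova", "nca", "nb")
CLASSIFIERS = ("svm", "mlp")


@dataclass
class RunConfig:
    """Everything one experiment needs, serializable to YAML."""

    seed: int = 0
    models: tuple[str, ...] = MODEL_IDS
    selectors: tuple[str, ...] = SELECTORS
    classifiers: tuple[str, ...] = CLASSIFIERS
    k_values: dict = field(default_factory=lambda: dict(DEFAULT_K))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    register: bool = True
    outlier_filter: bool = True
    global_selection: bool = False

    def validate(self) -> "RunConfig":
        for m in self.models:
            if m not in MODEL_IDS:
                raise ValidationError(f"unknown model {m!r}")
        for s in self.selectors:
            if s not in RANKERS:
                raise ValidationError(f"unknown selector {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValidationError(f"unknown classifier {c!r}")
        return self

    def grid(self) -> list[tuple[str, str, str]]:
        """All (model, classifier, selector) cells, report-row order."""
        return [
            (m, c, s) for m in self.models for c in self.classifiers for s in self.selectors
        ]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_dict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort_raw = raw.pop("cohort", {})
        occ = OcclusionSpec(**cohort_raw.pop("occlusion", {}))
        cohort = CohortConfig(occlusion=occ, **cohort_raw)
        cfg = cls(cohort=cohort, **raw)
        cfg.models = tuple(cfg.models)
        cfg.selectors = tuple(cfg.selectors)
        cfg.classifiers = tuple(cfg.classifiers)
        return cfg.validate()


def _config_dict(cfg: RunConfig) -> dict:
    cohort = {
        "n_per_class": dict(cfg.cohort.n_per_class),
        "jitter_sd": cfg.cohort.jitter_sd,
        "noise_sd": cfg.cohort.noise_sd,
        "occlusion": dataclasses.asdict(cfg.cohort.occlusion),
        "motion_rotation_max": cfg.cohort.motion_rotation_max,
        "motion_scale_max": cfg.cohort.motion_scale_max,
        "motion_shift_max": cfg.cohort.motion_shift_max,
        "subject_baseline_sd": cfg.cohort.subject_baseline_sd,
    }
    return {
        "seed": cfg.seed,
        "models": list(cfg.models),
        "selectors": list(cfg.selectors),
        "classifiers": list(cfg.classifiers),
        "k_values": dict(cfg.k_values),
        "register": cfg.register,
        "outlier_filter": cfg.outlier_filter,
        "global_selection": cfg.global_selection,
        "cohort": cohort,
    }


@dataclass
class ProcessedPair:
    """A registered pair plus the face bounding box used for ROI cropping."""

    subject_id: str
    pair: "object"
    face_bbox: tuple[int, int, int, int]
    transform: object | None = None


def preprocess_cohort(
    records: Sequence[CohortRecord], register: bool = True
) -> list[ProcessedPair]:
    """Face-extract each apex frame and register onset to apex coordinates.

    With ``register=False`` the onset frame is used as-is (appropriate when
    the generator applied no motion). Failures are logged and the subject is
    skipped, never silently dropped.
    """
    out = []
    for rec in records:
        try:
            face = extract_face(rec.pair.apex)
            if register:
                onset_reg, tform, _ = register_pair(rec.pair.onset, rec.pair.apex)
            else:
                onset_reg, tform = rec.pair.onset, None
            pair = dataclasses.replace(rec.pair, onset=onset_reg)
            out.append(ProcessedPair(rec.subject_id, pair, face.bbox, tform))
        except ThermaffectError as exc:
            logger.warning("preprocessing failed for %s: %s", rec.subject_id, exc)
    if not out:
        raise ThermaffectError("preprocessing failed for every subject")
    return out


def feature_tables(
    processed: Sequence[ProcessedPair],
    models: Sequence[str] = MODEL_IDS,
    outlier_filter: bool = True,
    provenance: dict | None = None,
) -> dict[str, FeatureTable]:
    """Build (and optionally outlier-filter) one feature table per model."""
    tables = {}
    for model in models:
        layout = build_layout(model)
        table = build_feature_table(processed, layout, provenance=provenance or {})
        if outlier_filter:
            table, removed = remove_outliers(table)
            if removed:
                logger.info("%s: removed %d outlier instances", model, len(removed))
        tables[model] = table
    return tables


def evaluate_cell(
    table: FeatureTable,
    selector: str,
    classifier: str | ClassifierSpec,
    k: int | None = None,
    seed: int = 0,
    global_selection: bool = False,
) -> EvaluationReport:
    """One (feature table, selector, classifier) cell of the result grid."""
    spec = classifier if isinstance(classifier, ClassifierSpec) else ClassifierSpec(classifier)
    tasks = make_binary_tasks(table, seed=seed)
    results = [
        run_task(t, spec, selector, k=k, seed=spawn_seed(seed, i), global_selection=global_selection)
        for i, t in enumerate(tasks)
    ]
    return aggregate(results)


@dataclass
class ExperimentResult:
    reports: dict  # (model, classifier, selector) -> EvaluationReport
    summaries: dict  # model -> DataFrame (rows classifier-selector, cols classes + mean)
    tables: dict  # model -> FeatureTable
    config: RunConfig
    out_dir: Path | None


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full analysis grid; write artifacts if ``out_dir`` given."""
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        (out / "versions.json").write_text(json.dumps(_versions(), indent=2))

    logger.info("stage 1/4: simulating cohort")
    records, manifest = generate_cohort(config.cohort, seed=spawn_seed(config.seed, 0))
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)

    logger.info("stage 2/4: preprocessing %d pairs", len(records))
    processed = preprocess_cohort(records, register=config.register)

    logger.info("stage 3/4: feature tables for %s", config.models)
    tables = feature_tables(
        processed,
        config.models,
        outlier_filter=config.outlier_filter,
        provenance={"seed": config.seed},
    )
    if out is not None:
        for model, table in tables.items():
            table.to_csv(out / f"features_{model}.csv")

    logger.info("stage 4/4: classification grid (%d cells)", len(config.grid()))
    reports, summaries = {}, {}
    for model in config.models:
        table = tables[model]
        # fold rankings are shared across classifier families within a cell row
        tasks = make_binary_tasks(table, seed=spawn_seed(config.seed, 5))
        rows = {}
        for selector in config.selectors:
            k = int(config.k_values.get(selector.upper(), DEFAULT_K[selector.upper()]))
            k = min(k, table.data.shape[1])
            rankings = [
                None
                if config.global_selection
                else compute_fold_rankings(t, selector, seed=spawn_seed(config.seed, 6, ti))
                for ti, t in enumerate(tasks)
            ]
            for classifier in config.classifiers:
                spec = ClassifierSpec(classifier)
                results = [
                    run_task(
                        t,
                        spec,
                        selector,
                        k=k,
                        seed=spawn_seed(config.seed, 7, ti),
                        global_selection=config.global_selection,
                        rankings=rankings[ti],
                    )
                    for ti, t in enumerate(tasks)
                ]
                report = aggregate(results)
                reports[(model, classifier, selector)] = report
                rows[f"{classifier.upper()}-{selector.upper()}"] = report.summary_row()
        summary = pd.DataFrame(rows).T
        summary = summary[[*sorted(EMOTIONS, key=list(EMOTIONS).index), "mean"]]
        summaries[model] = summary
        if out is not None:
            summary.to_csv(out / f"summary_{model}.csv")
            for (m, c, s), rep in reports.items():
                if m != model:
                    continue
                payload = {
                    "per_class": rep.per_class.to_dict(),
                    "overall": rep.overall,
                    "per_task": rep.per_task.to_dict(),
                }
                (out / f"report_{m}_{c}_{s}.json").write_text(
                    json.dumps(payload, indent=2)
                )
    if out is not None:
        try:
            plot_model_comparison(summaries, out / "model_comparison.png")
        except Exception as exc:  # plotting must never kill a finished run
            logger.warning("comparison figure failed: %s", exc)
    return ExperimentResult(reports, summaries, tables, config, out)


def plot_model_comparison(summaries: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Bar chart of overall mean accuracy per classifier-selector and model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = list(summaries)
    rows = summaries[models[0]].index
    x = np.arange(len(rows))
    width = 0.8 / len(models)
    fig, ax = plt.subplots(figsize=(9, 4))
    for i, model in enumerate(models):
        ax.bar(x + i * width, summaries[model]["mean"], width, label=model)
    ax.set_xticks(x + width * (len(models) - 1) / 2)
    ax.set_xticklabels(rows, rotation=45, ha="right")
    ax.set_ylabel("overall mean accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import numpy
    import pandas
    import skimage
    import sklearn

    from . import __version__

    return {
        "thermaffect": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
    }
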