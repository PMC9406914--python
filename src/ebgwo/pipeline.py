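"""End-to-end experiment orchestration.

The workflow: load a CSV feature table (or generate a synthetic cohort),
z-score standardize, stratified 75/25 split, run binary grey wolf
selection on the training partition, then evaluate every configured
classifier twice on the identical split — once on all columns
("baseline") and once on the selected columns ("proposed") — and write a
comparison report.

Standardization is fitted on the training partition only and applied to
both sides by default (leakage-correct); ``standardize_first=True`` instead
fits on the full table before splitting, reproducing the common
standardize-then-split protocol.  Every stochastic component draws its
seed from one master seed, so a report is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import eval_metrics, feature_io
from .ebgwo_selector import FitnessSpec, SelectionResult, select_features
from .eval_metrics import ClassifierSpec
from .feature_io import FeatureTable
from .gwo_engine import GWOConfig
from .synthetic_cohort import CohortSpec, default_schema, generate_cohort

__all__ = ["RunConfig", "EvalReport", "run_experiment", "write_report"]

logger = logging.getLogger("ebgwo")

REPORT_COLUMNS = [
    "classifier",
    "variant",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "auc",
    "n_features",
    "wall_time",
]


def default_classifiers(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(kind, seed=seed) for kind in eval_metrics.CLASSIFIER_KINDS]


@dataclass
class RunConfig:
    """One experiment: data source, split, selection and evaluation."""

    data_path: str | None = None
    cohort: CohortSpec | None = None
    test_fraction: float = 0.25
    standardize_first: bool = False
    group_by_subject: bool = False
    gwo: GWOConfig = field(default_factory=GWOConfig)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    classifiers: list[ClassifierSpec] = field(default_factory=default_classifiers)
    seed: int = 0
    label_column: str = "class"
    id_column: str = "id"

    def __post_init__(self) -> None:
        if self.data_path is None and self.cohort is None:
            self.cohort = CohortSpec()
        if not self.classifiers:
            raise ValueError("no classifiers configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "data_path",
            "test_fraction",
            "standardize_first",
            "group_by_subject",
            "seed",
            "label_column",
            "id_column",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "gwo" in raw:
            kwargs["gwo"] = GWOConfig(**raw["gwo"])
        if "fitness" in raw:
            fs = dict(raw["fitness"])
            if "validation" in fs:
                from .ebgwo_selector import ValidationScheme

                fs["validation"] = ValidationScheme(**fs["validation"])
            kwargs["fitness"] = FitnessSpec(**fs)
        if "classifiers" in raw:
            kwargs["classifiers"] = [
                ClassifierSpec(**c) if isinstance(c, dict) else ClassifierSpec(c)
                for c in raw["classifiers"]
            ]
        return cls(**kwargs)


@dataclass
class EvalReport:
    """Baseline-vs-proposed comparison plus the selection summary."""

    rows: list[dict[str, Any]]
    selection: SelectionResult
    confusions: dict[str, dict[str, int]]
    n_total_features: int
    config_snapshot: dict[str, Any]

    @property
    def reduction(self) -> float:
        return 1.0 - self.selection.n_selected / self.n_total_features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=REPORT_COLUMNS)

    def to_dict(self, include_wall_time: bool = True) -> dict[str, Any]:
        rows = self.rows
        if not include_wall_time:
            rows = [{k: v for k, v in r.items() if k != "wall_time"} for r in rows]
        return {
            "rows": rows,
            "selection": {
                "n_selected": self.selection.n_selected,
                "n_total": self.n_total_features,
                "reduction": self.reduction,
                "best_fitness": self.selection.best_fitness,
            },
            "confusions": self.confusions,
            "config": self.config_snapshot,
        }


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % 2**31]


def _load_table(config: RunConfig, cohort_seed: int) -> FeatureTable:
    if config.data_path is not None:
        logger.info("loading feature table from %s", config.data_path)
        return feature_io.read_feature_table(
            config.data_path,
            label_column=config.label_column,
            id_column=config.id_column,
        )
    cohort = dataclasses.replace(config.cohort, seed=cohort_seed)
    logger.info(
        "generating synthetic cohort: %d cases, %d controls, %d recordings each",
        cohort.n_cases,
        cohort.n_controls,
        cohort.recordings_per_subject,
    )
    table, _truth = generate_cohort(default_schema(), cohort)
    return table


def run_experiment(config: RunConfig) -> EvalReport:
    """Execute the full workflow and return the comparison report."""
    cohort_seed, split_seed, gwo_seed, clf_seed = _child_seeds(config.seed, 4)
    if config.cohort is not None and config.data_path is None and config.cohort.seed:
        cohort_seed = config.cohort.seed  # explicit cohort seed wins

    stage = "load"
    try:
        table = _load_table(config, cohort_seed)
        n_missing = feature_io.check_missing(table)
        logger.info("missing-value audit: %d missing cells", n_missing)

        stage = "split"
        if config.standardize_first:
            params = feature_io.standardize_fit(table)
            table = feature_io.standardize_apply(table, params)
        train, test = feature_io.stratified_split(
            table,
            config.test_fraction,
            split_seed,
            group_by_subject=config.group_by_subject,
        )
        stage = "standardize"
        if not config.standardize_first:
            params = feature_io.standardize_fit(train)
            train = feature_io.standardize_apply(train, params)
            test = feature_io.standardize_apply(test, params)
        logger.info("split: train %d rows, test %d rows", train.n_rows, test.n_rows)

        stage = "select"
        gwo = dataclasses.replace(config.gwo, dim=train.n_features, seed=gwo_seed)
        selection = select_features(train, gwo, config.fitness)
        logger.info(
            "selected %d / %d features (reduction %.1f%%), best fitness %.5f",
            selection.n_selected,
            train.n_features,
            100 * (1 - selection.n_selected / train.n_features),
            selection.best_fitness,
        )

        stage = "evaluate"
        rows: list[dict[str, Any]] = []
        confusions: dict[str, dict[str, int]] = {}
        sel_mask = selection.mask.astype(bool)
        for clf in config.classifiers:
            clf = dataclasses.replace(clf, seed=clf_seed)
            for variant, tr, te in (
                ("baseline", train, test),
                ("proposed", train.select_features(sel_mask), test.select_features(sel_mask)),
            ):
                t0 = time.perf_counter()
                preds, scores = eval_metrics.fit_predict(clf, tr, te)
                wall = time.perf_counter() - t0
                cm = eval_metrics.confusion(te.labels, preds)
                metrics = eval_metrics.classification_metrics(cm)
                auc = eval_metrics.auc_rank(
                    eval_metrics.ScoredPredictions(scores, te.labels)
                )
                rows.append(
                    {
                        "classifier": clf.kind,
                        "variant": variant,
                        **metrics,
                        "auc": auc,
                        "n_features": tr.n_features,
                        "wall_time": wall,
                    }
                )
                confusions[f"{clf.kind}_{variant}"] = cm.to_dict()
                logger.info(
                    "%s/%s: accuracy %.3f, auc %.3f (%d features)",
                    clf.kind,
                    variant,
                    metrics["accuracy"],
                    auc,
                    tr.n_features,
                )
    except Exception:
        logger.exception("stage %r failed (master seed %d)", stage, config.seed)
        raise

    snapshot = {
        "seed": config.seed,
        "test_fraction": config.test_fraction,
        "standardize_first": config.standardize_first,
        "group_by_subject": config.group_by_subject,
        "data_path": config.data_path,
        "cohort": dataclasses.asdict(config.cohort) if config.cohort else None,
        "selection": selection.config,
    }
    return EvalReport(
        rows=rows,
        selection=selection,
        confusions=confusions,
        n_total_features=train.n_features,
        config_snapshot=snapshot,
    )


def write_report(report: EvalReport, outdir) -> list[Path]:
    """Write report.csv / report.json / selection.json / trace.csv and the
    per-classifier confusion matrices into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = outdir / "report.csv"
    report.to_frame().to_csv(path, index=False)
    written.append(path)

    path = outdir / "report.json"
    path.write_text(json.dumps(report.to_dict(include_wall_time=False), indent=2))
    written.append(path)

    path = outdir / "selection.json"
    path.write_text(json.dumps(report.selection.to_dict(), indent=2))
    written.append(path)

    path = outdir / "trace.csv"
    pd.DataFrame(
        {
            "iteration": np.arange(report.selection.trace.shape[0]),
            "best_fitness": report.selection.trace,
            "n_selected": report.selection.trace_n_selected,
        }
    ).to_csv(path, index=False)
    written.append(path)

    for name, cm in report.confusions.items():
        path = outdir / f"confusion_{name}.json"
        path.write_text(json.dumps(cm, indent=2))
        written.append(path)
    return written
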