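"""End-to-end orchestration: series -> batches -> exclusion-fitted
class models -> score table -> feature ranking -> performance curves.

The downstream classifier is deliberately a single pluggable hook
(default: a linear-kernel C-support vector machine) — the point of the
method is the feature transformation, not classifier tuning.
Every stochastic step takes its seed from the run configuration and
all settings, class sizes and dropped-batch counts are recorded in a
plain-text run manifest, so a rerun with the same configuration is
diff-clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Hashable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_validate
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import make_pipeline
from sklearn.svm import SVC

from .class_model import ElementSample
from .exceptions import (
    EmptyTableError,
    SizeTooLargeError,
    SpecError,
    WisdomError,
)
from .scoring import ScoreMode, transform_dataset
from .timeseries import BatchSeries, batches_to_elements

__all__ = [
    "RunConfig",
    "make_classifier",
    "run_transform",
    "rank_features",
    "incremental_feature_curve",
    "subsample_stability",
]

CLASSIFIERS = {
    "linear_svm": lambda: SVC(kernel="linear"),
    "logistic": lambda: LogisticRegression(max_iter=5000),
    "random_forest": lambda: RandomForestClassifier(n_estimators=200),
}


def make_classifier(name: str = "linear_svm", **options):
    """Instantiate a downstream classifier by name, standardized
    features included. Options are forwarded to the estimator."""
    if name not in CLASSIFIERS:
        raise SpecError(f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}")
    est = CLASSIFIERS[name]()
    if options:
        est.set_params(**options)
    return make_pipeline(StandardScaler(), est)


@dataclass
class RunConfig:
    """Everything a transform run needs; every stochastic step's seed
    derives from ``seed`` and is echoed in the run manifest."""

    statistic: Literal["covariance", "correlation"] = "correlation"
    weighting: Literal["uniform", "dof_weighted"] = "dof_weighted"
    exclusion: Literal["leave_one_out", "k_fold"] = "leave_one_out"
    k: int = 10
    mode: ScoreMode = "literal"
    classifier: str = "linear_svm"
    classifier_options: dict = field(default_factory=dict)
    cv_folds: int = 10
    center: bool = True
    ddof: int = 0
    ridge: float = 0.0
    seed: int = 0


def run_transform(
    batches: Sequence[BatchSeries],
    config: RunConfig,
) -> tuple[pd.DataFrame, dict]:
    """Execute timeseries -> class models -> score-vector transform.

    Returns the score table and a run manifest (settings, class sizes,
    dropped-batch count). Failures are re-raised with the pipeline
    stage named, so a bad input file is distinguishable from a
    numerical failure during scoring.
    """
    manifest: dict = {"config": asdict(config)}
    try:
        elements, dropped = batches_to_elements(
            batches,
            statistic=config.statistic,
            center=config.center,
            ddof=config.ddof,
            ridge=config.ridge,
        )
    except WisdomError as exc:
        raise type(exc)(f"[stage: matrix extraction] {exc}") from exc
    manifest["n_batches"] = len(batches)
    manifest["n_dropped_short"] = dropped
    counts = pd.Series([e.label for e in elements]).value_counts()
    manifest["class_sizes"] = {str(k): int(v) for k, v in counts.items()}

    names = batches[0].channel_names if batches else None
    try:
        table = transform_dataset(
            elements,
            exclusion=config.exclusion,
            k=config.k,
            shuffle_seed=config.seed,
            weighting=config.weighting,
            mode=config.mode,
            feature_names=names,
        )
    except WisdomError as exc:
        raise type(exc)(f"[stage: scoring transform] {exc}") from exc
    manifest["n_scored"] = len(table)
    return table, manifest


def ratio_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("ratio_")]


def rank_features(table: pd.DataFrame) -> pd.DataFrame:
    """Rank features by mean |Ratio_j| over elements, descending;
    ties break toward the lower original feature index."""
    cols = ratio_columns(table)
    if table.empty or not cols:
        raise EmptyTableError("score table has no rows or no ratio columns")
    stat = table[cols].abs().mean(axis=0)
    order = sorted(range(len(cols)), key=lambda i: (-stat.iloc[i], i))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(cols) + 1),
            "feature": [cols[i][len("ratio_"):] for i in order],
            "column": [cols[i] for i in order],
            "mean_abs_ratio": [stat.iloc[i] for i in order],
        }
    )


def _cv_performance(
    x: np.ndarray,
    y: np.ndarray,
    classifier_name: str,
    classifier_options: dict,
    cv_folds: int,
    seed: int,
) -> dict[str, float]:
    clf = make_classifier(classifier_name, **classifier_options)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    res = cross_validate(clone(clf), x, y, cv=cv, scoring=["accuracy", "roc_auc"])
    return {
        "accuracy": float(np.mean(res["test_accuracy"])),
        "roc_auc": float(np.mean(res["test_roc_auc"])),
    }


def incremental_feature_curve(
    table: pd.DataFrame,
    ranking: pd.DataFrame | None = None,
    classifier: str = "linear_svm",
    classifier_options: dict | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated performance of the top-k ranked ratio features,
    k = 1..p. The k = p row is full-feature performance by definition."""
    if ranking is None:
        ranking = rank_features(table)
    y = _binary_labels(table)
    rows = []
    for k in range(1, len(ranking) + 1):
        cols = list(ranking["column"].iloc[:k])
        perf = _cv_performance(
            table[cols].to_numpy(), y, classifier, classifier_options or {}, cv_folds, seed
        )
        rows.append({"k": k, "added_feature": ranking["feature"].iloc[k - 1], **perf})
    return pd.DataFrame(rows)


def _binary_labels(table: pd.DataFrame) -> np.ndarray:
    labels = sorted(table["label"].unique(), key=repr)
    if len(labels) != 2:
        raise SpecError(f"need exactly two classes, found {labels!r}")
    return (table["label"] == labels[1]).to_numpy().astype(int)


def subsample_stability(
    elements: Sequence[ElementSample],
    sizes: Sequence[int],
    repeats: int = 5,
    classifier: str = "linear_svm",
    classifier_options: dict | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and standard error of 5-fold CV accuracy/AUC over repeated
    equal-per-class subsamples, one row per requested size.

    The transform (with the configured exclusion) is re-run inside
    every subsample, so the reported spread includes the transform's
    own sensitivity to sample size — the quantity of interest when
    judging how much data the method needs.
    """
    if repeats < 2:
        raise SpecError(f"repeats must be >= 2, got {repeats}")
    config = config or RunConfig()
    by_class: dict[Hashable, list[ElementSample]] = {}
    for e in elements:
        by_class.setdefault(e.label, []).append(e)
    if len(by_class) != 2:
        raise SpecError(f"need exactly two classes, found {sorted(by_class, key=repr)!r}")
    min_class = min(len(v) for v in by_class.values())

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size < 2:
            raise SizeTooLargeError(f"per-class size must be >= 2, got {size}")
        if size > min_class:
            raise SizeTooLargeError(
                f"per-class size {size} exceeds smallest class ({min_class})"
            )
        accs, aucs = [], []
        for r in range(repeats):
            sub: list[ElementSample] = []
            for members in by_class.values():
                idx = rng.choice(len(members), size=size, replace=False)
                sub.extend(members[i] for i in idx)
            table = transform_dataset(
                sub,
                exclusion=config.exclusion,
                k=min(config.k, size),
                shuffle_seed=int(rng.integers(2**31)),
                weighting=config.weighting,
                mode=config.mode,
            )
            perf = _cv_performance(
                table[ratio_columns(table)].to_numpy(),
                _binary_labels(table),
                classifier,
                classifier_options or {},
                cv_folds=5,
                seed=int(rng.integers(2**31)),
            )
            accs.append(perf["accuracy"])
            aucs.append(perf["roc_auc"])
        rows.append(
            {
                "size_per_class": size,
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_se": float(np.std(accs, ddof=1) / np.sqrt(repeats)),
                "auc_mean": float(np.mean(aucs)),
                "auc_se": float(np.std(aucs, ddof=1) / np.sqrt(repeats)),
            }
        )
    return pd.DataFrame(rows)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Flat key-value text dump of a run manifest (nested dicts are
    dotted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _emit(prefix: str, obj, fh):
        for k, v in obj.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                _emit(key + ".", v, fh)
            else:
                fh.write(f"{key} = {v}\n")

    with open(path, "w") as fh:
        _emit("", manifest, fh)
    return path
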