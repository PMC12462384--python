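"""Training, cross-validation, persistence and application of the two-stage
classifier.

Stage 1 decides CPP vs non-CPP on the descriptor set surviving the
Mann-Whitney + extra-trees selection; stage 2 decides high vs low uptake
efficiency using the five atomic frequencies only, and is reported only for
peptides stage 1 calls positive.  The default learner is an
extremely-randomized-trees ensemble (500 unpruned trees, Gini impurity,
sqrt(d) candidate features per split, no bootstrap); random forest, gradient
boosting, SVM and MLP are selectable alternatives with no bespoke logic
(SVM/MLP are wrapped with per-column standardization fitted on training
folds only).

Model bundles persist as a directory: a JSON manifest (format version,
hyperparameters, ordered feature names, SHA-256 of each estimator file and
of the training data) plus joblib-serialized estimators.  Loading verifies
the hashes, and prediction refuses any matrix whose columns differ from the
training columns in name or order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import ATOMIC_NAMES, DescriptorConfig, featurize_all
from .errors import (
    ColumnMismatchError,
    CppkitError,
    HashMismatchError,
    SingleClassError,
    TooFewPerClassError,
    VersionMismatchError,
)
from .evaluation import MetricsReport, evaluate_predictions
from .matrix import FeatureMatrix
from .selection import SelectionReport, select_features
from .seqio import LabeledDataset

__all__ = [
    "TrainingParams",
    "ClassifierModel",
    "CVResult",
    "train",
    "predict",
    "cross_validate",
    "cross_validate_pipeline",
    "fit_two_stage",
    "predict_two_stage",
    "TwoStageBundle",
    "save_model",
    "load_model",
    "dataset_hash",
]

FORMAT_VERSION = 1
ALGORITHMS = ("ert", "rf", "gbt", "svm", "mlp")


@dataclass(frozen=True)
class TrainingParams:
    """Learner choice and hyperparameters; the seed is always recorded.

    ``extra`` is an open key-value map passed verbatim to the underlying
    estimator and stored verbatim in the model bundle.
    """

    algorithm: str = "ert"
    n_estimators: int = 500
    seed: int = 42
    class_weight: str = "none"  # "balanced" | "none"
    threshold: float = 0.5
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise CppkitError(f"algorithm must be one of {ALGORITHMS}")
        if self.class_weight not in ("balanced", "none"):
            raise CppkitError("class_weight must be 'balanced' or 'none'")
        if not 0.0 < self.threshold < 1.0:
            raise CppkitError("threshold must lie in (0, 1)")

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "class_weight": self.class_weight,
            "threshold": self.threshold,
            "extra": dict(self.extra),
        }


def build_estimator(params: TrainingParams):
    """Instantiate the scikit-learn (or xgboost) estimator for ``params``."""
    cw = "balanced" if params.class_weight == "balanced" else None
    if params.algorithm == "ert":
        return ExtraTreesClassifier(
            n_estimators=params.n_estimators,
            criterion="gini",
            max_features="sqrt",
            bootstrap=False,
            class_weight=cw,
            random_state=params.seed,
            n_jobs=1,
            **params.extra,
        )
    if params.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=params.n_estimators,
            class_weight=cw,
            random_state=params.seed,
            n_jobs=1,
            **params.extra,
        )
    if params.algorithm == "gbt":
        from xgboost import XGBClassifier  # optional dependency

        return XGBClassifier(
            n_estimators=params.n_estimators,
            random_state=params.seed,
            eval_metric="logloss",
            n_jobs=1,
            **params.extra,
        )
    if params.algorithm == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(probability=True, class_weight=cw,
                            random_state=params.seed, **params.extra)),
            ]
        )
    if params.algorithm == "mlp":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("mlp", MLPClassifier(random_state=params.seed, max_iter=500,
                                      **params.extra)),
            ]
        )
    raise CppkitError(f"unknown algorithm {params.algorithm!r}")


@dataclass
class ClassifierModel:
    """A fitted classifier bound to an exact ordered feature-name list."""

    stage: str  # "cpp" | "efficiency"
    params: TrainingParams
    feature_names: list[str]
    estimator: object
    metadata: dict = field(default_factory=dict)

    def check_columns(self, m: FeatureMatrix) -> None:
        if list(m.names) != list(self.feature_names):
            raise ColumnMismatchError(
                f"matrix columns do not match the model's {len(self.feature_names)} "
                "training columns (name, order and count must be identical)"
            )


def _check_two_classes(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SingleClassError("training labels contain a single class")
    if counts.min() < 2:
        raise SingleClassError("each class needs at least 2 rows")


def train(
    m: FeatureMatrix, params: TrainingParams | None = None, stage: str = "cpp"
) -> ClassifierModel:
    """Fit a classifier on a labeled matrix; deterministic for a fixed seed."""
    if m.labels is None:
        raise SingleClassError("training matrix carries no labels")
    params = params if params is not None else TrainingParams()
    _check_two_classes(m.labels)
    estimator = build_estimator(params)
    estimator.fit(m.values, m.labels)
    metadata = {
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "n_rows": m.n_rows,
        "matrix_hash": _matrix_hash(m),
    }
    return ClassifierModel(
        stage=stage,
        params=params,
        feature_names=list(m.names),
        estimator=estimator,
        metadata=metadata,
    )


def predict(model: ClassifierModel, m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class scores and hard labels at the model's threshold."""
    model.check_columns(m)
    proba = model.estimator.predict_proba(m.values)
    classes = list(getattr(model.estimator, "classes_", [0, 1]))
    scores = proba[:, classes.index(1)]
    labels = (scores >= model.params.threshold).astype(int)
    return scores, labels


@dataclass
class CVResult:
    folds: list[MetricsReport]
    seed: int
    k: int

    def mean(self, metric: str) -> float:
        values = [getattr(r, metric) for r in self.folds]
        values = [v for v in values if v is not None]
        return float(np.mean(values)) if values else float("nan")

    def std(self, metric: str) -> float:
        values = [getattr(r, metric) for r in self.folds]
        values = [v for v in values if v is not None]
        return float(np.std(values)) if values else float("nan")

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in ("sn", "sp", "acc", "pr", "f1", "mcc", "auc"):
            out[metric] = {"mean": self.mean(metric), "std": self.std(metric)}
        return out


def _folds(labels: np.ndarray, k: int, seed: int) -> StratifiedKFold:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SingleClassError("cross-validation needs both classes")
    if counts.min() < k:
        raise TooFewPerClassError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def cross_validate(
    m: FeatureMatrix,
    params: TrainingParams | None = None,
    k: int = 10,
    seed: int = 42,
) -> CVResult:
    """Stratified k-fold cross-validation on a fixed feature matrix.

    Per-fold metrics are computed on the held-out fold only; the aggregate
    is the mean over folds.
    """
    if m.labels is None:
        raise SingleClassError("matrix carries no labels")
    params = params if params is not None else TrainingParams()
    splitter = _folds(m.labels, k, seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(m.values, m.labels):
        estimator = clone(build_estimator(params))
        estimator.fit(m.values[train_idx], m.labels[train_idx])
        proba = estimator.predict_proba(m.values[test_idx])
        classes = list(estimator.classes_)
        scores = proba[:, classes.index(1)]
        predicted = (scores >= params.threshold).astype(int)
        reports.append(
            evaluate_predictions(m.labels[test_idx], predicted, scores)
        )
    return CVResult(folds=reports, seed=seed, k=k)


def cross_validate_pipeline(
    m: FeatureMatrix,
    params: TrainingParams | None = None,
    alpha: float = 0.05,
    top_k: int = 522,
    k: int = 10,
    seed: int = 42,
) -> CVResult:
    """Cross-validate the full selection + classification pipeline.

    The Mann-Whitney filter and the extra-trees ranking are refitted inside
    every training fold, so held-out folds never inform feature selection
    and the fold metrics are unbiased.
    """
    if m.labels is None:
        raise SingleClassError("matrix carries no labels")
    params = params if params is not None else TrainingParams()
    splitter = _folds(m.labels, k, seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(m.values, m.labels):
        fold_train = FeatureMatrix(
            ids=[m.ids[i] for i in train_idx],
            names=list(m.names),
            values=m.values[train_idx],
            labels=m.labels[train_idx],
        )
        selected, report = select_features(
            fold_train, alpha=alpha, top_k=top_k,
            n_estimators=params.n_estimators, seed=params.seed,
        )
        if not report.selected:  # nothing survived: predict the majority class
            majority = int(np.bincount(m.labels[train_idx]).argmax())
            predicted = np.full(len(test_idx), majority)
            scores = np.full(len(test_idx), 0.5)
            reports.append(
                evaluate_predictions(m.labels[test_idx], predicted, scores)
            )
            continue
        model = train(selected, params)
        fold_test = FeatureMatrix(
            ids=[m.ids[i] for i in test_idx],
            names=list(m.names),
            values=m.values[test_idx],
            labels=m.labels[test_idx],
        ).subset(report.selected)
        scores, predicted = predict(model, fold_test)
        reports.append(
            evaluate_predictions(m.labels[test_idx], predicted, scores)
        )
    return CVResult(folds=reports, seed=seed, k=k)


# ---------------------------------------------------------------------------
# two-stage bundle


@dataclass
class TwoStageBundle:
    stage1: ClassifierModel
    stage2: ClassifierModel
    selection: SelectionReport
    config: DescriptorConfig

    def __post_init__(self) -> None:
        if list(self.stage2.feature_names) != list(ATOMIC_NAMES):
            raise ColumnMismatchError(
                f"stage-2 model must use exactly the atomic features {ATOMIC_NAMES}"
            )


def dataset_hash(ds: LabeledDataset) -> str:
    """SHA-256 over canonicalized (id, sequence, label) triples."""
    digest = hashlib.sha256()
    for p in ds:
        digest.update(f"{p.id}\t{p.sequence}\t{p.label}\n".encode())
    return digest.hexdigest()


def _matrix_hash(m: FeatureMatrix) -> str:
    digest = hashlib.sha256()
    digest.update("\t".join(m.names).encode())
    digest.update(np.ascontiguousarray(np.round(m.values, 9)).tobytes())
    if m.labels is not None:
        digest.update(np.ascontiguousarray(m.labels).tobytes())
    return digest.hexdigest()


def fit_two_stage(
    train_cpp: LabeledDataset,
    train_eff: LabeledDataset,
    cfg: DescriptorConfig | None = None,
    alpha: float = 0.05,
    top_k: int = 522,
    params: TrainingParams | None = None,
) -> TwoStageBundle:
    """Fit both stages from labeled peptide datasets.

    Stage 1: featurize -> Mann-Whitney filter -> ERT ranking -> ERT fit.
    Stage 2: atomic frequencies -> ERT fit (on the efficiency dataset, where
    label 1 means high uptake efficiency).
    """
    cfg = cfg if cfg is not None else DescriptorConfig()
    params = params if params is not None else TrainingParams()
    matrix = featurize_all(train_cpp, cfg)
    selected, report = select_features(
        matrix, alpha=alpha, top_k=top_k,
        n_estimators=params.n_estimators, seed=params.seed,
    )
    if not report.selected:
        raise CppkitError("stage 1: no feature passed the Mann-Whitney filter")
    stage1 = train(selected, params, stage="cpp")
    stage1.metadata["dataset_hash"] = dataset_hash(train_cpp)

    atomic_cfg = DescriptorConfig(
        blocks=("ATOMIC",), pka_table=cfg.pka_table,
        gravy_scale=cfg.gravy_scale,
        hydrophobicity_scale=cfg.hydrophobicity_scale,
        net_charge_ph=cfg.net_charge_ph, normalize_by=cfg.normalize_by,
    )
    eff_matrix = featurize_all(train_eff, atomic_cfg)
    stage2 = train(eff_matrix, params, stage="efficiency")
    stage2.metadata["dataset_hash"] = dataset_hash(train_eff)
    return TwoStageBundle(stage1=stage1, stage2=stage2, selection=report, config=cfg)


def predict_two_stage(bundle: TwoStageBundle, ds: LabeledDataset) -> pd.DataFrame:
    """Apply the bundle to peptides.

    Stage-2 scores are reported only for stage-1 positives; for stage-1
    negatives the efficiency columns are explicitly not applicable (NaN /
    <NA>), never a silent score.
    """
    matrix = featurize_all(ds, bundle.config)
    stage1_in = matrix.subset(bundle.stage1.feature_names)
    s1_scores, s1_labels = predict(bundle.stage1, stage1_in)
    atomic = matrix.subset(list(ATOMIC_NAMES))
    s2_scores = np.full(len(ds), np.nan)
    s2_labels = np.full(len(ds), np.nan)
    positives = np.flatnonzero(s1_labels == 1)
    if positives.size:
        atomic_pos = FeatureMatrix(
            ids=[atomic.ids[i] for i in positives],
            names=list(atomic.names),
            values=atomic.values[positives],
        )
        scores, labels = predict(bundle.stage2, atomic_pos)
        s2_scores[positives] = scores
        s2_labels[positives] = labels
    return pd.DataFrame(
        {
            "id": ds.ids,
            "stage1_score": s1_scores,
            "stage1_label": s1_labels,
            "stage2_score": s2_scores,
            "stage2_label": pd.array(
                [None if np.isnan(v) else int(v) for v in s2_labels],
                dtype="Int64",
            ),
        }
    )


# ---------------------------------------------------------------------------
# persistence


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_entry(model: ClassifierModel, directory: Path, name: str) -> dict:
    estimator_file = directory / f"{name}.joblib"
    joblib.dump(model.estimator, estimator_file)
    return {
        "stage": model.stage,
        "params": model.params.as_dict(),
        "feature_names": model.feature_names,
        "metadata": model.metadata,
        "estimator_file": estimator_file.name,
        "estimator_sha256": _sha256_file(estimator_file),
    }


def save_model(bundle: TwoStageBundle, path: str | Path) -> None:
    """Persist a two-stage bundle to a directory (manifest + estimators)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": "two-stage",
        "stage1": _model_entry(bundle.stage1, directory, "stage1"),
        "stage2": _model_entry(bundle.stage2, directory, "stage2"),
    }
    bundle.selection.to_json(directory / "selection.json")
    bundle.config.to_yaml(directory / "descriptor_config.yaml")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_entry(entry: dict, directory: Path) -> ClassifierModel:
    estimator_file = directory / entry["estimator_file"]
    actual = _sha256_file(estimator_file)
    if actual != entry["estimator_sha256"]:
        raise HashMismatchError(
            f"{estimator_file.name}: manifest hash {entry['estimator_sha256'][:12]}… "
            f"but file hashes to {actual[:12]}…"
        )
    estimator = joblib.load(estimator_file)
    model = ClassifierModel(
        stage=entry["stage"],
        params=TrainingParams(**entry["params"]),
        feature_names=list(entry["feature_names"]),
        estimator=estimator,
        metadata=dict(entry.get("metadata", {})),
    )
    n_expected = getattr(estimator, "n_features_in_", None)
    if n_expected is not None and n_expected != len(model.feature_names):
        raise HashMismatchError(
            f"manifest lists {len(model.feature_names)} features but the "
            f"estimator was fitted on {n_expected}"
        )
    return model


def load_model(path: str | Path) -> TwoStageBundle:
    """Load a bundle saved by :func:`save_model`, verifying version and hashes."""
    directory = Path(path)
    manifest = json.loads((directory / "manifest.json").read_text())
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise VersionMismatchError(
            f"bundle format version {version!r}; this build reads {FORMAT_VERSION}"
        )
    selection = SelectionReport.from_json(directory / "selection.json")
    config = DescriptorConfig.from_yaml(directory / "descriptor_config.yaml")
    return TwoStageBundle(
        stage1=_load_entry(manifest["stage1"], directory),
        stage2=_load_entry(manifest["stage2"], directory),
        selection=selection,
        config=config,
    )
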