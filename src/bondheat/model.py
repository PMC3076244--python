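"""Linear max-margin classifier on sparse binary fingerprints.

The optimization is delegated to scikit-learn's liblinear-backed
``LinearSVC`` (L2-regularized hinge loss, bias term included); this module
owns the feature-id bookkeeping, the rare-feature filter, hyperparameter
search and the repeated two-deep cross-validation protocol.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .fingerprint import (
    DEFAULT_DEPTH,
    DEFAULT_HASH_BITS,
    ProvenancedFingerprint,
)

DEFAULT_MIN_COUNT = 3
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 9))
DEFAULT_W_GRID = tuple(2.0 ** k for k in (-4, -2, 0))

MODEL_FORMAT_VERSION = 1


class ModelError(Exception):
    pass


class ConfigMismatchError(ModelError):
    """Fingerprint was computed with a different configuration than the model."""


class SolverError(ModelError):
    pass


class FeatureFilterError(ModelError):
    pass


class ModelFormatError(ModelError):
    pass


@dataclass
class LabeledDataset:
    """Index-aligned fingerprints and {+1, -1} labels."""

    fingerprints: list[ProvenancedFingerprint]
    labels: np.ndarray
    removed_features: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.fingerprints) != len(self.labels):
            raise ValueError("fingerprints and labels differ in length")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}, got extra {bad}")

    def __len__(self) -> int:
        return len(self.fingerprints)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            fingerprints=[self.fingerprints[i] for i in indices],
            labels=self.labels[list(indices)],
            removed_features=self.removed_features,
        )

    def feature_space(self) -> list[int]:
        feats: set[int] = set()
        for fp in self.fingerprints:
            feats.update(fp.present_features)
        return sorted(feats)

    def to_matrix(self, feature_index: dict[int, int]) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, fp in enumerate(self.fingerprints):
            for fid in fp.present_features:
                j = feature_index.get(fid)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
        data = np.ones(len(rows))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.fingerprints), len(feature_index))
        )


@dataclass
class LinearModel:
    """Linear discriminant f(x) = w.x + bias over fingerprint features.

    Features absent from ``weights`` have weight exactly 0.
    """

    weights: dict[int, float]
    bias: float
    C: float
    negative_class_weight: float
    depth: int = DEFAULT_DEPTH
    hash_bits: int = DEFAULT_HASH_BITS
    min_count: int = DEFAULT_MIN_COUNT

    def check_config(self, fp: ProvenancedFingerprint) -> None:
        if fp.depth != self.depth or fp.hash_bits != self.hash_bits:
            raise ConfigMismatchError(
                f"fingerprint config (depth={fp.depth}, hash_bits={fp.hash_bits}) "
                f"does not match model config (depth={self.depth}, "
                f"hash_bits={self.hash_bits})"
            )


@dataclass
class EvalReport:
    """Per-repeat, per-fold performance of the two-deep cross-validation."""

    table: pd.DataFrame  # columns: repeat, fold, C, negative_class_weight, auc, acc

    @property
    def mean_auc(self) -> float:
        return float(self.table["auc"].mean())

    @property
    def mean_acc(self) -> float:
        return float(self.table["acc"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def filter_rare_features(data: LabeledDataset, min_count: int = DEFAULT_MIN_COUNT) -> LabeledDataset:
    """Drop features present in fewer than ``min_count`` molecules.

    Provenance is retained on every fingerprint; only feature presence is
    reduced, and the removed ids are recorded on the returned dataset.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if min_count == 1:
        return data
    counts: dict[int, int] = {}
    for fp in data.fingerprints:
        for fid in fp.present_features:
            counts[fid] = counts.get(fid, 0) + 1
    keep = {fid for fid, c in counts.items() if c >= min_count}
    removed = frozenset(counts) - keep
    if counts and not keep:
        raise FeatureFilterError(
            f"min_count={min_count} removed every feature from the dataset"
        )
    new_fps = []
    for fp in data.fingerprints:
        new_fps.append(
            ProvenancedFingerprint(
                molecule=fp.molecule,
                depth=fp.depth,
                hash_bits=fp.hash_bits,
                present_features=fp.present_features & keep,
                provenance=fp.provenance,
                substructure_table=fp.substructure_table,
            )
        )
    return LabeledDataset(
        fingerprints=new_fps,
        labels=data.labels,
        removed_features=data.removed_features | removed,
    )


def _check_config_consistency(data: LabeledDataset) -> tuple[int, int]:
    configs = {(fp.depth, fp.hash_bits) for fp in data.fingerprints}
    if len(configs) != 1:
        raise ConfigMismatchError(f"mixed fingerprint configs in dataset: {configs}")
    return configs.pop()


def train(
    data: LabeledDataset,
    C: float,
    negative_class_weight: float = 1.0,
    seed: int = 0,
    min_count: int = DEFAULT_MIN_COUNT,
    _keep_estimator: bool = False,
) -> LinearModel:
    """Fit the linear SVM and extract per-feature weights.

    ``negative_class_weight`` multiplies the misclassification cost C for
    negative-class examples.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    classes = set(np.unique(data.labels))
    if classes != {-1, 1}:
        raise ModelError("training requires both classes present")
    depth, hash_bits = _check_config_consistency(data)
    features = data.feature_space()
    feature_index = {fid: j for j, fid in enumerate(features)}
    X = data.to_matrix(feature_index)
    clf = LinearSVC(
        C=C,
        loss="hinge",
        penalty="l2",
        dual=True,
        class_weight={-1: negative_class_weight, 1: 1.0},
        fit_intercept=True,
        intercept_scaling=1.0,
        tol=1e-8,
        max_iter=200_000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, data.labels)
        except ConvergenceWarning as exc:
            raise SolverError(f"liblinear-style solver did not converge: {exc}") from exc
    coef = clf.coef_.ravel()
    # sklearn orders decision_function by classes_ = [-1, 1]; coef_ already
    # corresponds to the +1 class for binary problems
    weights = {fid: float(coef[j]) for fid, j in feature_index.items() if coef[j] != 0.0}
    model = LinearModel(
        weights=weights,
        bias=float(clf.intercept_[0]),
        C=C,
        negative_class_weight=negative_class_weight,
        depth=depth,
        hash_bits=hash_bits,
        min_count=min_count,
    )
    if _keep_estimator:
        model._estimator = clf  # type: ignore[attr-defined]
        model._feature_index = feature_index  # type: ignore[attr-defined]
    return model


def decision_value(model: LinearModel, fp: ProvenancedFingerprint) -> float:
    """f(x) = bias + sum of weights over present features (binary x).

    Features unknown to the model contribute 0.
    """
    model.check_config(fp)
    terms = [model.weights[fid] for fid in fp.present_features if fid in model.weights]
    return model.bias + math.fsum(terms)


def decision_values(model: LinearModel, fps: Sequence[ProvenancedFingerprint]) -> np.ndarray:
    return np.array([decision_value(model, fp) for fp in fps])


def select_hyperparameters(
    data: LabeledDataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    W_grid: Sequence[float] = DEFAULT_W_GRID,
    seed: int = 0,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[float, float]:
    """Grid search by inner 2-fold cross-validated AUC.

    The inner split is fixed once per scan; ties are broken toward the
    smallest C, then the smallest class weight.
    """
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(data)), data.labels))
    best: Optional[tuple[float, float, float]] = None  # (auc, C, W)
    for C in sorted(C_grid):
        for W in sorted(W_grid):
            aucs = []
            for train_idx, test_idx in splits:
                inner_train = filter_rare_features(data.subset(train_idx), min_count)
                m = train(inner_train, C=C, negative_class_weight=W, seed=seed,
                          min_count=min_count)
                scores = decision_values(m, [data.fingerprints[i] for i in test_idx])
                aucs.append(roc_auc_score(data.labels[test_idx], scores))
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, C, W)
    assert best is not None
    return best[1], best[2]


def evaluate(
    data: LabeledDataset,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    W_grid: Sequence[float] = DEFAULT_W_GRID,
    min_count: int = DEFAULT_MIN_COUNT,
) -> EvalReport:
    """Repeated stratified k-fold two-deep cross-validation.

    Rare-feature filtering and hyperparameter selection see only the outer
    training portion of each fold; AUC and ACC are measured on the held-out
    fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rows = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        try:
            splits = list(skf.split(np.zeros(len(data)), data.labels))
        except ValueError as exc:
            raise ModelError(f"stratification failed: {exc}") from exc
        for f, (train_idx, test_idx) in enumerate(splits):
            outer_train = data.subset(train_idx)
            if len(set(data.labels[test_idx])) < 2:
                raise ModelError(f"fold {f} of repeat {r} is missing a class")
            C, W = select_hyperparameters(
                outer_train, C_grid=C_grid, W_grid=W_grid,
                seed=seed + 1000 * r + f, min_count=min_count,
            )
            filtered = filter_rare_features(outer_train, min_count)
            m = train(filtered, C=C, negative_class_weight=W,
                      seed=seed + 1000 * r + f, min_count=min_count)
            scores = decision_values(m, [data.fingerprints[i] for i in test_idx])
            y_true = data.labels[test_idx]
            rows.append(
                {
                    "repeat": r,
                    "fold": f,
                    "C": C,
                    "negative_class_weight": W,
                    "auc": roc_auc_score(y_true, scores),
                    "acc": accuracy_score(y_true, np.where(scores >= 0, 1, -1)),
                }
            )
    return EvalReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: LinearModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "weights": {str(fid): w for fid, w in sorted(model.weights.items())},
        "bias": model.bias,
        "C": model.C,
        "negative_class_weight": model.negative_class_weight,
        "depth": model.depth,
        "hash_bits": model.hash_bits,
        "min_count": model.min_count,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> LinearModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    try:
        if doc["format_version"] != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {doc['format_version']}"
            )
        return LinearModel(
            weights={int(fid): float(w) for fid, w in doc["weights"].items()},
            bias=float(doc["bias"]),
            C=float(doc["C"]),
            negative_class_weight=float(doc["negative_class_weight"]),
            depth=int(doc["depth"]),
            hash_bits=int(doc["hash_bits"]),
            min_count=int(doc["min_count"]),
        )
    except KeyError as exc:
        raise ModelFormatError(f"model file {path} is missing field {exc}") from exc


# ---------------------------------------------------------------------------
# Sparse dataset I/O (presence-only fingerprints, no provenance)
# ---------------------------------------------------------------------------


def read_sparse_dataset(
    path,
    depth: int = DEFAULT_DEPTH,
    hash_bits: int = DEFAULT_HASH_BITS,
) -> LabeledDataset:
    """Read ``label id:1 ...`` lines into a dataset of presence-only
    fingerprints (empty provenance; sufficient for training)."""
    fps = []
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            try:
                label = int(parts[0])
                feats = frozenset(int(tok.split(":")[0]) for tok in parts[1:])
            except (ValueError, IndexError) as exc:
                raise ModelError(f"{path}:{lineno}: bad sparse line") from exc
            if label not in (-1, 1):
                raise ModelError(f"{path}:{lineno}: label must be +1 or -1")
            fps.append(
                ProvenancedFingerprint(
                    molecule=None,  # type: ignore[arg-type]
                    depth=depth,
                    hash_bits=hash_bits,
                    present_features=feats,
                    provenance={},
                    substructure_table={},
                )
            )
            labels.append(label)
    if not fps:
        raise ModelError(f"no records in {path}")
    return LabeledDataset(fingerprints=fps, labels=np.array(labels))
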