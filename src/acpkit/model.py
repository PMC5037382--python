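"""RBF-kernel support-vector classification with grid-searched (C, γ).

The classifier follows the standard LibSVM-style recipe for peptide
classification: features are min-max scaled to [0, 1] with parameters fit
on the *training* rows only, then an RBF-kernel SVC is trained; (C, γ) are
chosen by exhaustive grid search maximizing mean stratified k-fold accuracy,
with ties broken toward the smallest C, then the smallest γ.

Labels are the strings ``"positive"`` (anticancer) and ``"negative"``; the
decision function is oriented so that positive decision values mean the
positive class, with the tie at exactly 0 resolved as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import EncodedMatrix

#: Conventional LibSVM grid: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3 (step 2^2).
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))

MODEL_FORMAT_TAG = "acpkit-model-1"


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, EncodedMatrix):
        return matrix.X
    return np.asarray(matrix, dtype=float)


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    labels = list(labels)
    bad = [l for l in labels if l not in ("positive", "negative")]
    if bad:
        raise ValueError(f"labels must be 'positive'/'negative', got {bad[0]!r}")
    return np.array([1 if l == "positive" else 0 for l in labels], dtype=int)


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature (min, max) pairs fit on training rows only."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins/maxs must be 1-d arrays of equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaling parameters")

    @property
    def n_features(self) -> int:
        return self.mins.size

    def transform(self, X) -> np.ndarray:
        """(x - min) / (max - min), no clipping; constant features map to 0."""
        X = _as_array(X)
        span = self.maxs - self.mins
        out = np.zeros_like(X, dtype=float)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / span[nz]
        return out


def fit_scaler(matrix) -> ScalerParams:
    """Per-feature min and max from the given rows only."""
    X = _as_array(matrix)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters plus the training-set scaling."""

    C: float
    gamma: float
    scaling: ScalerParams
    kernel: str = "RBF"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.kernel != "RBF":
            raise ValueError("only the RBF kernel is supported")


@dataclass
class TrainedModel:
    """A fitted decision function over the scaled feature space."""

    spec: ModelSpec
    feature_names: list[str]
    svc: SVC
    encoder_meta: dict = field(default_factory=dict)


def grid_search(
    matrix,
    labels: Sequence[str],
    c_values: Sequence[float] = DEFAULT_C_GRID,
    gamma_values: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (C, γ) search by mean stratified k-fold accuracy.

    Scaling is re-fit inside every fold on its training portion.  The search
    is deterministic given ``seed``; among tied accuracies the smallest C,
    then the smallest γ, wins.
    """
    X = _as_array(matrix)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes present")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best: tuple[float, float] | None = None
    best_acc = -np.inf
    for C, gamma in product(sorted(c_values), sorted(gamma_values)):
        correct = 0
        for train_idx, test_idx in splits:
            scaler = fit_scaler(X[train_idx])
            svc = SVC(C=C, gamma=gamma, kernel="rbf")
            svc.fit(scaler.transform(X[train_idx]), y[train_idx])
            dv = svc.decision_function(scaler.transform(X[test_idx]))
            correct += int(np.sum((dv >= 0).astype(int) == y[test_idx]))
        acc = correct / len(y)
        if acc > best_acc:
            best_acc = acc
            best = (C, gamma)
    assert best is not None
    return best


def train(matrix: EncodedMatrix, labels: Sequence[str], spec: ModelSpec) -> TrainedModel:
    """Fit the SVC on scaled features; positive class = anticancer."""
    X = _as_array(matrix)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both classes present")
    if spec.scaling.n_features != X.shape[1]:
        raise ValueError(
            f"column mismatch: scaling has {spec.scaling.n_features} features, "
            f"matrix has {X.shape[1]}"
        )
    svc = SVC(C=spec.C, gamma=spec.gamma, kernel="rbf")
    svc.fit(spec.scaling.transform(X), y)
    feature_names = (
        list(matrix.feature_names)
        if isinstance(matrix, EncodedMatrix)
        else [f"f{i}" for i in range(X.shape[1])]
    )
    meta = matrix.encoder_meta if isinstance(matrix, EncodedMatrix) else {}
    return TrainedModel(
        spec=spec, feature_names=feature_names, svc=svc, encoder_meta=dict(meta)
    )


def fit_model(
    matrix: EncodedMatrix,
    labels: Sequence[str],
    C: float,
    gamma: float,
) -> TrainedModel:
    """Convenience: fit scaler on ``matrix`` then train with (C, γ)."""
    spec = ModelSpec(C=C, gamma=gamma, scaling=fit_scaler(matrix))
    return train(matrix, labels, spec)


def decision_values(model: TrainedModel, matrix) -> np.ndarray:
    if isinstance(matrix, EncodedMatrix):
        if list(matrix.feature_names) != list(model.feature_names):
            for got, want in zip(matrix.feature_names, model.feature_names):
                if got != want:
                    raise ValueError(
                        f"feature-name mismatch: matrix has {got!r} where the "
                        f"model expects {want!r}"
                    )
            raise ValueError(
                f"feature-name mismatch: matrix has {len(matrix.feature_names)} "
                f"columns, model expects {len(model.feature_names)}"
            )
    X = _as_array(matrix)
    if X.shape[0] == 0:
        return np.empty(0)
    return model.svc.decision_function(model.spec.scaling.transform(X))


def predict(model: TrainedModel, matrix) -> tuple[list[str], np.ndarray]:
    """Per-row labels and decision values; decision >= 0 means positive."""
    dv = decision_values(model, matrix)
    labels = ["positive" if v >= 0 else "negative" for v in dv]
    return labels, dv


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format": MODEL_FORMAT_TAG,
            "C": model.spec.C,
            "gamma": model.spec.gamma,
            "mins": model.spec.scaling.mins,
            "maxs": model.spec.scaling.maxs,
            "feature_names": list(model.feature_names),
            "encoder_meta": dict(model.encoder_meta),
            "svc": model.svc,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format") != MODEL_FORMAT_TAG:
        raise ValueError(
            f"not an acpkit model file (format tag {payload.get('format')!r})"
        )
    spec = ModelSpec(
        C=payload["C"],
        gamma=payload["gamma"],
        scaling=ScalerParams(mins=payload["mins"], maxs=payload["maxs"]),
    )
    return TrainedModel(
        spec=spec,
        feature_names=list(payload["feature_names"]),
        svc=payload["svc"],
        encoder_meta=dict(payload.get("encoder_meta", {})),
    )
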