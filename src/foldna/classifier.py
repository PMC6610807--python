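"""Logistic-regression foldability model.

The foldability of a sequence-structure pair is the logistic model's
positive-class probability on the pair's feature vector; a pair is called
foldable when that probability strictly exceeds the threshold (0.5 by
default).  A small L2 penalty (lambda = 1e-4) keeps the fit finite on
collinear or separable data.  Model files are JSON and embed the feature
preset, the training min-max normalization record, and the energy-backend
fingerprint — scoring features produced under a different backend is refused
unless explicitly overridden, because energies are model-relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FoldabilityModel",
    "EvalReport",
    "BackendMismatchError",
    "train",
    "foldability",
    "classify",
    "loo_cross_validate",
    "evaluate",
]

MODEL_SCHEMA_VERSION = 1


class BackendMismatchError(RuntimeError):
    pass


@dataclass(frozen=True)
class FoldabilityModel:
    preset: str
    feature_names: tuple[str, ...]
    weights: np.ndarray  # per-feature coefficients
    intercept: float
    normalization: dict[str, np.ndarray]  # 'min' / 'max' per feature
    backend_fingerprint: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weight count does not match feature count")
        for key in ("min", "max"):
            if len(self.normalization[key]) != len(self.feature_names):
                raise ValueError("normalization columns do not match features")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": MODEL_SCHEMA_VERSION,
                "preset": self.preset,
                "feature_names": list(self.feature_names),
                "weights": [float(w) for w in self.weights],
                "intercept": float(self.intercept),
                "normalization": {
                    "min": [float(v) for v in self.normalization["min"]],
                    "max": [float(v) for v in self.normalization["max"]],
                },
                "backend_fingerprint": self.backend_fingerprint,
                "metadata": self.metadata,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldabilityModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {doc.get('schema_version')}")
        return cls(
            preset=doc["preset"],
            feature_names=tuple(doc["feature_names"]),
            weights=np.array(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            normalization={
                "min": np.array(doc["normalization"]["min"], dtype=float),
                "max": np.array(doc["normalization"]["max"], dtype=float),
            },
            backend_fingerprint=doc["backend_fingerprint"],
            metadata=doc.get("metadata", {}),
        )

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.normalization["min"], self.normalization["max"]
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        out = (np.asarray(X, dtype=float) - lo) / safe
        out[..., span == 0] = 0.0
        return out


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts with sensitivity/specificity; undefined rates are None."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def balanced_accuracy(self) -> float | None:
        se, sp = self.sensitivity, self.specificity
        if se is None or sp is None:
            return None
        return 0.5 * (se + sp)


def train(
    X: np.ndarray,
    y: np.ndarray,
    preset: str,
    feature_names: tuple[str, ...],
    normalization: dict[str, np.ndarray] | None = None,
    backend_fingerprint: str = "builtin-v1",
    reg_strength: float = 1e-4,
    seed: int = 0,
    metadata: dict | None = None,
) -> FoldabilityModel:
    """Fit the logistic foldability model on (already normalized) features.

    ``normalization`` is the min-max record produced during training-set
    assembly; it is stored, not re-derived, so prediction re-applies exactly
    the training scaling.  When omitted, an identity record is stored (the
    caller asserts features are already on a common scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature count does not match names")
    clf = LogisticRegression(
        C=1.0 / (reg_strength * len(y)),
        solver="lbfgs",
        max_iter=5000,
        tol=1e-8,
        random_state=seed,
    )
    clf.fit(X, y)
    if normalization is None:
        m = X.shape[1]
        normalization = {"min": np.zeros(m), "max": np.ones(m)}
    return FoldabilityModel(
        preset=preset,
        feature_names=tuple(feature_names),
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        normalization=normalization,
        backend_fingerprint=backend_fingerprint,
        metadata={"reg_strength": reg_strength, "seed": seed, **(metadata or {})},
    )


def foldability(
    model: FoldabilityModel,
    x: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    backend_fingerprint: str | None = None,
    allow_backend_mismatch: bool = False,
) -> float:
    """Foldability score in (0, 1): sigmoid of the linear model on normalized x."""
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError(
            f"feature columns {feature_names} do not match model {model.feature_names}"
        )
    if (
        backend_fingerprint is not None
        and backend_fingerprint != model.backend_fingerprint
        and not allow_backend_mismatch
    ):
        raise BackendMismatchError(
            f"features from backend {backend_fingerprint!r} scored against a model "
            f"trained with {model.backend_fingerprint!r}"
        )
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(model.feature_names):
        raise ValueError("feature row length does not match model")
    z = float(model._normalize(x) @ model.weights + model.intercept)
    # keep the score in the open interval even where the sigmoid saturates
    return float(np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1.0 - 1e-12))


def classify(model: FoldabilityModel, x: np.ndarray, threshold: float = 0.5) -> bool:
    """Foldable iff foldability strictly exceeds the threshold."""
    return foldability(model, x) > threshold


def evaluate(predictions, labels) -> EvalReport:
    """Confusion counts from boolean predictions against boolean labels."""
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError("prediction and label lengths differ")
    tp = sum(1 for p, t in zip(predictions, labels) if p and t)
    tn = sum(1 for p, t in zip(predictions, labels) if not p and not t)
    fp = sum(1 for p, t in zip(predictions, labels) if p and not t)
    fn = sum(1 for p, t in zip(predictions, labels) if not p and t)
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)


def loo_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    preset: str = "custom",
    feature_names: tuple[str, ...] | None = None,
    reg_strength: float = 1e-4,
    threshold: float = 0.5,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-out cross validation: n refits, each scoring its held-out row."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 2:
        raise ValueError("need at least 2 examples")
    names = (
        tuple(feature_names)
        if feature_names is not None
        else tuple(f"f{k}" for k in range(X.shape[1]))
    )
    preds = []
    for held in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[held] = False
        if len(np.unique(y[mask])) < 2:
            # held-out row removed the only example of a class; the refit is
            # impossible, count the row as misclassified
            preds.append(not bool(y[held]))
            continue
        m = train(
            X[mask],
            y[mask],
            preset=preset,
            feature_names=names,
            reg_strength=reg_strength,
            seed=seed,
        )
        preds.append(classify(m, X[held], threshold=threshold))
    return evaluate(preds, [bool(v) for v in y])
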