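"""Blending ensemble.

Three tuned base learners are fitted on the training split. Their predicted
class probabilities on the held-out internal-validation split become nine
meta-feature columns (model-major, class-minor) appended to the original
feature space, and a metamodel of one of the same families — reusing its
tuned hyperparameters — is trained on that widened matrix with the
internal-validation labels. At prediction time the base models' probabilities
on the new rows are appended the same way and the metamodel produces the
final class probabilities; the label is the argmax, ties resolved toward the
lowest class index.

The metamodel never sees training-split rows at fit time and never sees test
or independent labels; guards enforce the split hygiene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from maap.features import ScalerParams, apply_scaler
from maap.io import FeatureMatrix
from maap.modeling import LearnerSpec, train
from maap.splits import DatasetSplits

N_CLASSES = 3


def _predict_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(np.asarray(X, dtype=float))
    if proba.shape[1] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES}-class probabilities, got {proba.shape}")
    return proba


def meta_column_names(families: list[str]) -> list[str]:
    return [f"meta{m}_{fam}_p{c}"
            for m, fam in enumerate(families) for c in range(N_CLASSES)]


def build_meta_features(base_models: list[tuple[str, object]],
                        X: FeatureMatrix) -> FeatureMatrix:
    """Append each base model's class probabilities as meta-feature columns.

    Output width = width(X) + n_models x 3, columns tagged `meta_probability`
    and ordered model-major then class 0, 1, 2.
    """
    expected = getattr(base_models[0][1], "n_features_in_", X.shape[1])
    if X.shape[1] != expected:
        raise ValueError(
            f"input has {X.shape[1]} columns but base models expect {expected}"
        )
    blocks = [X.values] + [_predict_proba(m, X.values) for _, m in base_models]
    names = list(X.column_names) + meta_column_names([fam for fam, _ in base_models])
    roles = list(X.column_roles) + ["meta_probability"] * (N_CLASSES * len(base_models))
    return FeatureMatrix(row_keys=list(X.row_keys), column_names=names,
                         column_roles=roles, values=np.hstack(blocks))


class BlendingClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style blending ensemble over plain arrays.

    Parameters
    ----------
    base_specs : list of LearnerSpec
        Exactly three tuned base-learner configurations.
    meta_spec : LearnerSpec
        Metamodel configuration (typically the tuned spec of one base family).
    """

    def __init__(self, base_specs=None, meta_spec=None):
        self.base_specs = base_specs
        self.meta_spec = meta_spec

    def fit(self, X, y, X_val=None, y_val=None):
        if self.base_specs is None or len(self.base_specs) != 3:
            raise ValueError("base_specs must list exactly 3 learner specs")
        if self.meta_spec is None:
            raise ValueError("meta_spec is required")
        if X_val is None or y_val is None:
            raise ValueError(
                "blending needs a held-out internal-validation split (X_val, y_val)"
            )
        X = np.asarray(X, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y = np.asarray(y, dtype=int)
        y_val = np.asarray(y_val, dtype=int)
        self.base_models_ = [(spec.family, train(spec, X, y))
                             for spec in self.base_specs]
        meta_X = np.hstack([X_val] + [_predict_proba(m, X_val)
                                      for _, m in self.base_models_])
        self.metamodel_ = train(self.meta_spec, meta_X, y_val)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.arange(N_CLASSES)
        self.meta_column_order_ = meta_column_names(
            [fam for fam, _ in self.base_models_])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; fitted on {self.n_features_in_}"
            )
        meta_X = np.hstack([X] + [_predict_proba(m, X) for _, m in self.base_models_])
        return _predict_proba(self.metamodel_, meta_X)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)  # argmax ties -> lowest class


@dataclass
class BlendedModel:
    """Fitted blending ensemble bound to a feature-column manifest and scaler."""

    classifier: BlendingClassifier
    original_column_names: list[str]
    original_column_roles: list[str]
    scaler: ScalerParams | None = None
    seeds: dict = field(default_factory=dict)

    @property
    def meta_column_order(self) -> list[str]:
        return self.classifier.meta_column_order_

    def _check_manifest(self, X: FeatureMatrix) -> None:
        if X.column_names != self.original_column_names:
            raise ValueError("feature-column manifest mismatch; refusing to predict")

    def predict(self, X: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Predict labels and class probabilities for raw (unscaled) features."""
        self._check_manifest(X)
        if self.scaler is not None:
            X = apply_scaler(X, self.scaler)
        proba = self.classifier.predict_proba(X.values)
        return np.argmax(proba, axis=1), proba

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "families": [fam for fam, _ in self.classifier.base_models_],
            "meta_family": self.classifier.meta_spec.family,
            "meta_column_order": self.meta_column_order,
            "original_column_names": self.original_column_names,
            "original_column_roles": self.original_column_roles,
            "scaler": self.scaler.as_dict() if self.scaler else None,
            "seeds": self.seeds,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                                 encoding="utf-8")
        joblib.dump(self.classifier, directory / "classifier.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "BlendedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
        classifier = joblib.load(directory / "classifier.joblib")
        scaler = (ScalerParams.from_dict(manifest["scaler"])
                  if manifest["scaler"] else None)
        return cls(classifier=classifier,
                   original_column_names=manifest["original_column_names"],
                   original_column_roles=manifest["original_column_roles"],
                   scaler=scaler, seeds=manifest.get("seeds", {}))


def train_blend(base_specs: list[LearnerSpec], meta_spec: LearnerSpec,
                splits: DatasetSplits, X: FeatureMatrix, y,
                scaler: ScalerParams | None = None) -> BlendedModel:
    """Fit the full blending ensemble on a feature matrix and its splits.

    Base models fit on the train split, the metamodel on the
    internal-validation split. *scaler* (fitted on the train split) is applied
    before any model sees the data and stored in the bundle.
    """
    overlap = set(splits.train) & set(splits.internal_val)
    if overlap:
        raise ValueError(
            f"train and internal-validation splits overlap: {sorted(overlap)[:5]}"
        )
    if not splits.internal_val:
        raise ValueError("internal-validation split is empty")
    y = np.asarray(y, dtype=int)
    Xs = apply_scaler(X, scaler) if scaler is not None else X
    clf = BlendingClassifier(base_specs=base_specs, meta_spec=meta_spec)
    clf.fit(Xs.values[splits.train], y[splits.train],
            X_val=Xs.values[splits.internal_val], y_val=y[splits.internal_val])
    return BlendedModel(classifier=clf,
                        original_column_names=list(X.column_names),
                        original_column_roles=list(X.column_roles),
                        scaler=scaler,
                        seeds={"split": splits.seed,
                               "model": base_specs[0].seed})


def feature_importance(model, feature_names: list[str],
                       feature_roles: list[str] | None = None,
                       top_k: int = 30) -> list[tuple[str, float, str]]:
    """Ranked (name, importance, role) list, importances normalized to sum 1.

    Works for any fitted learner exposing ``feature_importances_`` (the tree
    families); other families raise.
    """
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise ValueError(
            f"{type(model).__name__} does not expose feature importances"
        )
    imp = np.asarray(imp, dtype=float)
    if imp.shape[0] != len(feature_names):
        raise ValueError(
            f"{imp.shape[0]} importances for {len(feature_names)} feature names"
        )
    if (imp < 0).any():
        raise ValueError("importances must be non-negative")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    roles = feature_roles or ["unknown"] * len(feature_names)
    order = np.argsort(-imp, kind="stable")
    ranked = [(feature_names[i], float(imp[i]), roles[i]) for i in order]
    return ranked[:top_k] if top_k is not None else ranked


def blended_feature_importance(model: BlendedModel, top_k: int = 30):
    """Importance ranking of the metamodel over original + meta columns."""
    names = model.original_column_names + model.meta_column_order
    roles = model.original_column_roles + ["meta_probability"] * len(model.meta_column_order)
    return feature_importance(model.classifier.metamodel_, names, roles, top_k=top_k)
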