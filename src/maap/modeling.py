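"""Base-learner registry, seeded training, and hyperparameter search.

Six learner families are registered: the two gradient-boosting families
(XGBoost, LightGBM), random forest, k-nearest neighbours, logistic regression
and an optional multilayer perceptron. Tuning is a seeded random search over
the YAML-declared spaces in ``search_spaces.yaml``: each trial samples one
configuration and scores it by mean macro F1 over stratified 3-fold
cross-validation (default) or on a held-out internal-validation set
(``objective_mode='holdout'``). The full trial log is returned and the best
configuration is refit on all provided rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from maap.metrics import macro_f1

FAMILIES = ("xgboost", "lightgbm", "random_forest", "knn", "logistic", "mlp")
CORE_FAMILIES = ("xgboost", "lightgbm", "random_forest")


def _load_spaces() -> dict:
    with resources.files("maap").joinpath("search_spaces.yaml").open() as fh:
        return yaml.safe_load(fh)


_SPACES = _load_spaces()


@dataclass
class LearnerSpec:
    """A learner family plus a concrete hyperparameter assignment."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unregistered family {self.family!r}; known: {FAMILIES}")
        space = _SPACES[self.family]
        for name, value in self.hyperparameters.items():
            if name not in space:
                raise ValueError(
                    f"{self.family}: hyperparameter {name!r} not in declared space"
                )
            rule = space[name]
            if rule["type"] in ("int", "float", "logfloat"):
                if not (rule["low"] <= value <= rule["high"]):
                    raise ValueError(
                        f"{self.family}.{name}={value} outside "
                        f"[{rule['low']}, {rule['high']}]"
                    )


def make_learner(spec: LearnerSpec):
    """Instantiate the estimator for a spec with deterministic settings."""
    hp = dict(spec.hyperparameters)
    if spec.family == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            objective="multi:softprob", num_class=3, tree_method="hist",
            n_jobs=1, random_state=spec.seed, verbosity=0, **hp,
        )
    if spec.family == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            objective="multiclass", num_class=3, n_jobs=1,
            random_state=spec.seed, deterministic=True, force_row_wise=True,
            verbose=-1, **hp,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(n_jobs=1, random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(n_jobs=1, **hp)
    if spec.family == "logistic":
        hp.setdefault("max_iter", 2000)
        if "l1_ratio" in hp:
            return LogisticRegression(penalty="elasticnet", solver="saga",
                                      random_state=spec.seed, **hp)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.family == "mlp":
        from sklearn.neural_network import MLPClassifier

        hp.setdefault("max_iter", 500)
        if isinstance(hp.get("hidden_layer_sizes"), list):
            hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
        return MLPClassifier(random_state=spec.seed, **hp)
    raise ValueError(f"unregistered family {spec.family!r}")


def train(spec: LearnerSpec, X, y):
    """Fit a learner; every class 0/1/2 must be present in y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    present = set(np.unique(y).tolist())
    if present != {0, 1, 2}:
        raise ValueError(f"training labels must cover classes {{0,1,2}}, got {sorted(present)}")
    model = make_learner(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _sample_spec(family: str, rng: np.random.Generator, seed: int) -> LearnerSpec:
    hp = {}
    for name, rule in _SPACES[family].items():
        t = rule["type"]
        if t == "int":
            hp[name] = int(rng.integers(rule["low"], rule["high"] + 1))
        elif t == "float":
            hp[name] = float(rng.uniform(rule["low"], rule["high"]))
        elif t == "logfloat":
            hp[name] = float(np.exp(rng.uniform(np.log(rule["low"]),
                                                np.log(rule["high"]))))
        elif t == "categorical":
            hp[name] = rule["choices"][int(rng.integers(len(rule["choices"])))]
        else:
            raise ValueError(f"unknown space type {t!r}")
    return LearnerSpec(family=family, hyperparameters=hp, seed=seed)


@dataclass
class SearchResult:
    best_spec: LearnerSpec
    best_objective: float
    trial_log: list[tuple[LearnerSpec, float]]
    best_model: Any = None

    @property
    def best_cv_macro_f1(self) -> float:
        return self.best_objective


def cv_macro_f1(spec: LearnerSpec, X, y, folds: int = 3, seed: int = 0) -> float:
    """Mean macro F1 over stratified k-fold CV for one spec."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model = train(spec, X[tr], y[tr])
        scores.append(macro_f1(y[te], model.predict(X[te])))
    return float(np.mean(scores))


def tune(family: str, X, y, budget: int = 50, folds: int = 3, seed: int = 0,
         objective_mode: str = "cv", X_val=None, y_val=None,
         refit: bool = True) -> SearchResult:
    """Seeded random search maximising macro F1.

    ``objective_mode='cv'`` (default) scores each trial by mean macro F1 over
    *folds* stratified CV folds of (X, y); ``'holdout'`` fits on (X, y) and
    scores on (X_val, y_val). Ties on the objective keep the earliest trial.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=3)
    if objective_mode == "cv" and counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} samples for {folds}-fold CV; got {counts.tolist()}"
        )
    if objective_mode == "holdout" and (X_val is None or y_val is None):
        raise ValueError("holdout objective needs X_val and y_val")

    rng = np.random.default_rng(seed)
    log: list[tuple[LearnerSpec, float]] = []
    for _ in range(budget):
        spec = _sample_spec(family, rng, seed)
        if objective_mode == "cv":
            score = cv_macro_f1(spec, X, y, folds=folds, seed=seed)
        else:
            model = train(spec, X, y)
            score = macro_f1(np.asarray(y_val, dtype=int), model.predict(X_val))
        log.append((spec, score))

    best_idx = int(np.argmax([s for _, s in log]))
    best_spec, best_score = log[best_idx]
    best_model = train(best_spec, X, y) if refit else None
    return SearchResult(best_spec=best_spec, best_objective=best_score,
                        trial_log=log, best_model=best_model)
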