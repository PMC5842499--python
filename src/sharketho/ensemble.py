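"""The five base learners and the weighted probability-averaging voting ensemble.

Base learners (all emit per-class probabilities):

* ``LR``  — one-vs-rest logistic regression (L2, unit strength), on
  standardised features;
* ``ANN`` — multilayer perceptron with a single hidden layer of 100 ReLU
  nodes and a softmax output, on standardised features;
* ``RFG`` / ``RFE`` — random forests of 100 trees differing only in the
  split criterion (Gini impurity vs entropy);
* ``GB``  — gradient tree boosting, 100 trees of maximum depth 3.

The voting ensemble (VE) averages the members' class-probability matrices
with per-member weights (the best validation performer weighted three times
the others) and predicts the argmax class, ties breaking to the earlier
class in canonical order.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from sharketho.dataset import LabelledDataset
from sharketho.io import CLASSES, LabelTrack

KINDS = ("LR", "ANN", "RFG", "RFE", "GB")

#: learner kinds whose trees expose impurity-based feature importances
TREE_KINDS = ("RFG", "RFE", "GB")


@dataclass
class BaseLearnerSpec:
    """Configuration of one base learner."""

    kind: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown base learner kind {self.kind!r}; expected one of {KINDS}")


def default_specs(seed: int = 0) -> list[BaseLearnerSpec]:
    """One spec of each of the five kinds, seeds derived from ``seed``."""
    return [BaseLearnerSpec(kind=k, seed=seed + i) for i, k in enumerate(KINDS)]


def make_base_learner(spec: BaseLearnerSpec):
    """Instantiate an untrained scikit-learn estimator for a spec.

    Scale-sensitive learners (LR, ANN) are wrapped in a pipeline with a
    training-set standardiser; tree learners receive raw features.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "LR":
        # default sklearn penalty is L2; C=1 is unit regularisation strength
        est = OneVsRestClassifier(
            LogisticRegression(
                C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 1000),
                random_state=spec.seed, **hp,
            )
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.kind == "ANN":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100,)),
            activation="relu",
            max_iter=hp.pop("max_iter", 500),
            random_state=spec.seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.kind in ("RFG", "RFE"):
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            criterion="gini" if spec.kind == "RFG" else "entropy",
            max_features=hp.pop("max_features", "sqrt"),
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "GB":
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_depth=hp.pop("max_depth", 3),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=spec.seed,
            **hp,
        )
    raise ValueError(f"unknown base learner kind {spec.kind!r}")


@dataclass
class FittedLearner:
    """A fitted estimator plus the bookkeeping to emit canonical probabilities."""

    spec: BaseLearnerSpec
    estimator: object
    feature_names: tuple[str, ...]
    class_order: tuple[str, ...] = CLASSES

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = _check_columns(features, self.feature_names)
        raw = self.estimator.predict_proba(X)
        est = self.estimator
        classes = est.classes_ if hasattr(est, "classes_") else est[-1].classes_
        out = np.zeros((len(X), len(self.class_order)))
        for j, cls in enumerate(classes):
            out[:, self.class_order.index(cls)] = raw[:, j]
        # guard against OvR normalisation drift
        out /= out.sum(axis=1, keepdims=True)
        return out


def _check_columns(features: pd.DataFrame, expected: tuple[str, ...]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if tuple(features.columns) != tuple(expected):
            missing = set(expected) - set(features.columns)
            extra = set(features.columns) - set(expected)
            if missing or extra:
                raise ValueError(
                    f"feature columns do not match training layout "
                    f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
                )
            features = features[list(expected)]
        return features.to_numpy(dtype=float)
    arr = np.asarray(features, dtype=float)
    if arr.shape[1] != len(expected):
        raise ValueError(
            f"feature matrix has {arr.shape[1]} columns, training layout has {len(expected)}"
        )
    return arr


def train_all(specs: list[BaseLearnerSpec], train: LabelledDataset) -> list[FittedLearner]:
    """Fit every spec on the training split."""
    if len(set(train.labels)) < 2:
        raise ValueError("training set is degenerate: only one behaviour class present")
    fitted = []
    names = tuple(train.features.columns)
    X = train.features.to_numpy(dtype=float)
    for spec in specs:
        est = make_base_learner(spec)
        est.fit(X, train.labels.astype(str))
        fitted.append(FittedLearner(spec=spec, estimator=est, feature_names=names))
    return fitted


@dataclass
class TrainedEnsemble:
    """Fitted members plus per-member vote weights and the canonical class order."""

    members: list[FittedLearner]
    weights: np.ndarray
    class_order: tuple[str, ...] = CLASSES
    validation_macro_f: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        w = self.weights / self.weights.sum()
        probs = [m.predict_proba(features) for m in self.members]
        return np.tensordot(w, np.stack(probs), axes=1)

    def predict(self, features: pd.DataFrame, epoch_start=None) -> LabelTrack | np.ndarray:
        proba = self.predict_proba(features)
        # np.argmax returns the first maximum: ties break to the earlier
        # class in canonical order
        labels = np.array([self.class_order[i] for i in np.argmax(proba, axis=1)], dtype=object)
        if epoch_start is None:
            return labels
        return LabelTrack(labels=labels, epoch_start=epoch_start)

    def feature_importance(self) -> pd.DataFrame:
        """Normalised impurity importances, one column per tree-based member."""
        cols = {}
        for m in self.members:
            if m.spec.kind in TREE_KINDS:
                imp = np.asarray(m.estimator.feature_importances_, dtype=float)
                total = imp.sum()
                cols[m.spec.kind] = imp / total if total > 0 else imp
        if not cols:
            raise ValueError("ensemble has no tree-based member with feature importances")
        any_member = next(m for m in self.members if m.spec.kind in TREE_KINDS)
        return pd.DataFrame(cols, index=list(any_member.feature_names))

    def save(self, path) -> None:
        """Serialise to a directory: pickled members + a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "class_order": list(self.class_order),
            "weights": self.weights.tolist(),
            "members": [
                {"kind": m.spec.kind, "seed": m.spec.seed,
                 "hyperparameters": m.spec.hyperparameters}
                for m in self.members
            ],
            "feature_names": list(self.members[0].feature_names),
            "validation_macro_f": self.validation_macro_f,
        }
        (path / "ensemble.json").write_text(json.dumps(manifest, indent=2))
        with open(path / "members.pkl", "wb") as fh:
            pickle.dump(self.members, fh)

    @classmethod
    def load(cls, path) -> "TrainedEnsemble":
        path = Path(path)
        manifest = json.loads((path / "ensemble.json").read_text())
        with open(path / "members.pkl", "rb") as fh:
            members = pickle.load(fh)
        return cls(
            members=members,
            weights=np.array(manifest["weights"]),
            class_order=tuple(manifest["class_order"]),
            validation_macro_f=manifest.get("validation_macro_f", {}),
        )


def select_members(
    fitted: list[FittedLearner],
    validation: LabelledDataset,
    macro_f_floor: float = 0.0,
    best_weight: float = 3.0,
) -> TrainedEnsemble:
    """Rank members by validation macro-F and build the voting ensemble.

    Members below ``macro_f_floor`` are dropped; every survivor gets weight
    1 except the best performer, which is weighted ``best_weight`` (3 by
    default) so the others must agree confidently to override it.
    """
    from sharketho.metrics import confusion_counts, macro_f_from_counts

    if not fitted:
        raise ValueError("no fitted members supplied")
    scores = []
    for m in fitted:
        pred = np.array(
            [m.class_order[i] for i in np.argmax(m.predict_proba(validation.features), axis=1)],
            dtype=object,
        )
        cm = confusion_counts(validation.labels, pred, m.class_order)
        scores.append(macro_f_from_counts(cm))
    order = np.argsort(scores)[::-1]
    keep = [i for i in order if scores[i] >= macro_f_floor]
    if not keep:
        raise ValueError(f"no member reaches the macro-F floor of {macro_f_floor}")
    members = [fitted[i] for i in keep]
    weights = np.ones(len(keep))
    weights[0] = best_weight  # keep[0] is the top-ranked member
    return TrainedEnsemble(
        members=members,
        weights=weights,
        validation_macro_f={fitted[i].spec.kind: float(scores[i]) for i in keep},
    )
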