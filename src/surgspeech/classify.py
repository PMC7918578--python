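"""Per-segment phase classifiers and cross-validation.

Four supervised back-ends are supported, each with the hyperparameter
domain relevant to this problem:

* ``logreg`` — logistic regression in a one-versus-all scheme with a
  ridge (L2) penalty;
* ``svm`` — support vector machine with an RBF kernel and unit
  regularization parameter (C = 1), posteriors via pairwise-coupling
  calibration;
* ``rf`` — random forest with entropy or Gini split criterion,
  posteriors as tree-vote fractions;
* ``mlp`` — multilayer perceptron with logistic/tanh/relu activation
  and adam or lbfgs optimizer.

All back-ends expose calibrated posterior rows on the probability
simplex, which is what the downstream HMM consumes as emissions.

Cross-validation is stratified by phase at the segment level; inside
each fold, the vocabulary/embeddings, oversampling and classifier are
all fitted on the fold-train portion only, so no information leaks from
the validation portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .balance import svm_smote
from .corpus import Corpus
from .evaluate import confusion_matrix, prf_scores
from .features import make_extractor
from .preprocess import PreprocessConfig, preprocess_texts

__all__ = [
    "ClassifierSpec",
    "ClassifierModel",
    "CVReport",
    "train_classifier",
    "predict_posteriors",
    "cross_validate",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("logreg", "svm", "rf", "mlp")

_RF_CRITERIA = ("entropy", "gini")
_MLP_ACTIVATIONS = ("logistic", "tanh", "relu")
_MLP_OPTIMIZERS = ("adam", "lbfgs")


@dataclass(frozen=True)
class ClassifierSpec:
    """Kind plus kind-specific hyperparameters.

    Unlisted hyperparameters take conventional defaults: logreg ridge
    strength 1 (C = 1), rf 100 trees with unlimited depth, mlp a single
    hidden layer of 100 units.
    """

    kind: str = "svm"
    C: float = 1.0  # svm regularization / inverse ridge strength
    criterion: str = "entropy"  # rf
    n_trees: int = 100  # rf
    max_depth: int | None = None  # rf
    activation: str = "relu"  # mlp
    optimizer: str = "adam"  # mlp
    hidden: tuple[int, ...] = (100,)  # mlp
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )
        if self.kind == "rf" and self.criterion not in _RF_CRITERIA:
            raise ValueError(
                f"rf criterion must be one of {_RF_CRITERIA}, got {self.criterion!r}"
            )
        if self.kind == "mlp":
            if self.activation not in _MLP_ACTIVATIONS:
                raise ValueError(
                    f"mlp activation must be one of {_MLP_ACTIVATIONS}, "
                    f"got {self.activation!r}"
                )
            if self.optimizer not in _MLP_OPTIMIZERS:
                raise ValueError(
                    f"mlp optimizer must be one of {_MLP_OPTIMIZERS}, "
                    f"got {self.optimizer!r}"
                )

    def build(self):
        if self.kind == "logreg":
            return OneVsRestClassifier(
                LogisticRegression(
                    penalty="l2", C=self.C, max_iter=self.max_iter
                )
            )
        if self.kind == "svm":
            return SVC(
                kernel="rbf",
                C=self.C,
                gamma="scale",
                probability=True,
                random_state=self.seed,
            )
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion=self.criterion,
                max_depth=self.max_depth,
                random_state=self.seed,
            )
        return MLPClassifier(
            hidden_layer_sizes=self.hidden,
            activation=self.activation,
            solver=self.optimizer,
            max_iter=self.max_iter,
            random_state=self.seed,
        )

    def metadata(self) -> dict:
        meta = {"kind": self.kind, "seed": self.seed}
        if self.kind == "logreg":
            meta.update(scheme="one-vs-all", penalty="ridge", C=self.C)
        elif self.kind == "svm":
            meta.update(kernel="rbf", C=self.C,
                        posteriors="pairwise-coupling calibration")
        elif self.kind == "rf":
            meta.update(criterion=self.criterion, n_trees=self.n_trees,
                        max_depth=self.max_depth,
                        posteriors="tree-vote fractions")
        else:
            meta.update(activation=self.activation, optimizer=self.optimizer,
                        hidden=self.hidden)
        return meta


@dataclass
class ClassifierModel:
    """A fitted classifier with its ordered class list and train priors."""

    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray  # subset of 1..8 seen in training, sorted
    class_priors: np.ndarray  # training-label frequencies, same order
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = predict_posteriors(self, X)
        return self.classes[np.argmax(post, axis=1)]


def train_classifier(
    spec: ClassifierSpec, X: np.ndarray, y: Sequence[int]
) -> ClassifierModel:
    """Fit one classifier; deterministic under the spec's seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    est = spec.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    priors = counts / counts.sum()
    return ClassifierModel(
        spec=spec,
        estimator=est,
        classes=classes,
        class_priors=priors,
        n_features=X.shape[1],
    )


def predict_posteriors(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Posterior matrix with rows on the probability simplex; column
    order follows ``model.classes``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: got {X.shape}, "
            f"expected (*, {model.n_features})"
        )
    post = np.asarray(model.estimator.predict_proba(X), dtype=float)
    # guard against tiny calibration drift off the simplex
    post = np.clip(post, 0.0, None)
    post /= post.sum(axis=1, keepdims=True)
    return post


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return prf_scores(confusion_matrix(y_true, y_pred))["macro_f1"]


@dataclass
class CVReport:
    """Per-fold train/validation macro-F1 with summary statistics."""

    spec_meta: dict
    feature_name: str
    folds: int
    train_scores: list[float]
    val_scores: list[float]
    fold_meta: list[dict] = field(default_factory=list)
    overfit_threshold: float = 0.15

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.train_scores))

    @property
    def train_sd(self) -> float:
        return float(np.std(self.train_scores, ddof=1))

    @property
    def val_mean(self) -> float:
        return float(np.mean(self.val_scores))

    @property
    def val_sd(self) -> float:
        return float(np.std(self.val_scores, ddof=1))

    @property
    def overfitting(self) -> bool:
        return (self.train_mean - self.val_mean) > self.overfit_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [self.spec_meta["kind"]] * 2,
                "feature": [self.feature_name] * 2,
                "subset": ["train", "validation"],
                "mean_f1": [self.train_mean, self.val_mean],
                "sd_f1": [self.train_sd, self.val_sd],
            }
        )


def cross_validate(
    spec: ClassifierSpec,
    feature_name: str,
    corpus: Corpus,
    folds: int = 10,
    seed: int = 0,
    preprocess_config: PreprocessConfig | None = None,
    balance: bool = True,
    smote_k: int = 5,
    feature_params: dict | None = None,
) -> CVReport:
    """Stratified k-fold CV of one (classifier, feature set) pair.

    Every fold refits the feature extractor and (optionally) SVM-SMOTE
    on its own training portion; the per-fold metadata records the
    fitted sizes so the refitting is auditable.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(corpus):
        raise ValueError(f"folds={folds} exceeds corpus size {len(corpus)}")
    tokens = preprocess_texts(corpus.texts(), preprocess_config)
    y = corpus.labels()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    train_scores: list[float] = []
    val_scores: list[float] = []
    fold_meta: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # tiny-class fold warnings
        splits = list(skf.split(np.zeros(len(y)), y))
    for fold_id, (tr, va) in enumerate(splits):
        tok_tr = [tokens[i] for i in tr]
        tok_va = [tokens[i] for i in va]
        extractor = make_extractor(
            feature_name, seed=seed + fold_id, **(feature_params or {})
        )
        extractor.fit(tok_tr)
        X_tr = extractor.transform(tok_tr).values
        X_va = extractor.transform(tok_va).values
        y_tr, y_va = y[tr], y[va]
        meta = {
            "fold": fold_id,
            "n_fit_docs": len(tok_tr),
            "extractor": extractor.name,
        }
        if hasattr(extractor, "vocab") and extractor.vocab is not None:
            meta["vocab_size"] = extractor.vocab.size
            meta["vocab_n_docs"] = extractor.vocab.n_docs
        if balance:
            target = int(np.bincount(y_tr).max())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                X_fit, y_fit = svm_smote(
                    X_tr, y_tr, target, k=smote_k, seed=seed + fold_id
                )
            meta["balanced_to"] = target
            meta["n_after_balance"] = len(y_fit)
        else:
            X_fit, y_fit = X_tr, y_tr
        model = train_classifier(spec, X_fit, y_fit)
        train_scores.append(_macro_f1(y_tr, model.predict(X_tr)))
        val_scores.append(_macro_f1(y_va, model.predict(X_va)))
        fold_meta.append(meta)
    return CVReport(
        spec_meta=spec.metadata(),
        feature_name=feature_name,
        folds=folds,
        train_scores=train_scores,
        val_scores=val_scores,
        fold_meta=fold_meta,
    )
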