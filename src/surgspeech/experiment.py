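"""End-to-end experiment runner.

Wires the full pipeline together: video-level train/test split,
preprocessing, feature fitting on the training split, SVM-SMOTE
balancing of training features, classifier training, optional HMM
coupling with per-video Viterbi decoding, and evaluation of both the
raw per-segment predictions and the smoothed timelines.

All randomness derives from one root seed: the feature extractor,
oversampler and classifier receive ``seed + 1``, ``seed + 2`` and
``seed + 3`` respectively, so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .balance import svm_smote
from .classify import (
    CLASSIFIER_KINDS,
    ClassifierModel,
    ClassifierSpec,
    CVReport,
    cross_validate,
    predict_posteriors,
    train_classifier,
)
from .corpus import Corpus, split_corpus
from .evaluate import EvalReport, evaluate_predictions, timeline_report
from .features import FEATURE_NAMES, make_extractor
from .preprocess import PreprocessConfig, preprocess_texts
from .temporal import (
    DecodedTimeline,
    TransitionModel,
    estimate_transitions,
    posteriors_to_emissions,
    viterbi,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "run_grid"]


@dataclass
class ExperimentConfig:
    """Everything needed to run one (feature, classifier) experiment."""

    feature: str = "word2vec"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    test_video_ids: tuple[str, ...] = ()
    feature_params: dict = field(default_factory=dict)
    balance: bool = True
    balance_target: int | None = None  # None: majority class of the train split
    smote_k: int = 5
    hmm: bool = True
    hmm_alpha: float = 0.01
    emission_mode: str = "scaled_likelihood"
    emission_floor: float = 1e-6
    extra_boost: float = 0.0
    cv_folds: int = 0  # 0 disables cross-validation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(
                f"unknown feature set {self.feature!r}; choose from {FEATURE_NAMES}"
            )

    def resolved(self) -> dict:
        out = asdict(self)
        out["classifier"] = self.classifier.metadata()
        return out


@dataclass
class ExperimentResult:
    """Outputs of one experiment run."""

    config: dict
    raw_report: EvalReport
    hmm_report: EvalReport | None
    timelines: list[DecodedTimeline]
    per_video: dict[str, dict]
    transition_model: TransitionModel | None
    model: ClassifierModel
    cv_report: CVReport | None

    def summary_row(self) -> dict:
        report = self.hmm_report if self.hmm_report is not None else self.raw_report
        return {
            "feature": self.config["feature"],
            "classifier": self.config["classifier"]["kind"],
            "hmm": self.hmm_report is not None,
            "macro_f1": report.macro_f1,
            "accuracy": report.accuracy,
        }


def run_experiment(corpus: Corpus, config: ExperimentConfig) -> ExperimentResult:
    if not config.test_video_ids:
        raise ValueError("config.test_video_ids must name the held-out videos")
    train, test = split_corpus(corpus, config.test_video_ids)
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both train and test splits must be non-empty")

    tokens_train = preprocess_texts(train.texts(), config.preprocess)
    tokens_test = preprocess_texts(test.texts(), config.preprocess)
    y_train = train.labels()
    y_test = test.labels()

    extractor = make_extractor(
        config.feature, seed=config.seed + 1, **config.feature_params
    )
    extractor.fit(tokens_train)
    X_train = extractor.transform(tokens_train).values
    X_test = extractor.transform(tokens_test).values

    if config.balance:
        target = config.balance_target
        if target is None:
            target = int(np.bincount(y_train).max())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_fit, y_fit = svm_smote(
                X_train, y_train, target, k=config.smote_k, seed=config.seed + 2
            )
    else:
        X_fit, y_fit = X_train, y_train

    spec = ClassifierSpec(**{**_spec_kwargs(config.classifier),
                             "seed": config.seed + 3})
    model = train_classifier(spec, X_fit, y_fit)

    raw_pred = model.predict(X_test)
    raw_report = evaluate_predictions(y_test, raw_pred)

    hmm_report = None
    timelines: list[DecodedTimeline] = []
    per_video: dict[str, dict] = {}
    tm: TransitionModel | None = None
    if config.hmm:
        tm = estimate_transitions(train.label_sequences(), alpha=config.hmm_alpha)
        if config.extra_boost > 0:
            tm = tm.boost_extra(config.extra_boost)
        smoothed: list[int] = []
        by_video = test.by_video()
        offsets: dict[str, slice] = {}
        pos = 0
        for vid, segs in by_video.items():
            offsets[vid] = slice(pos, pos + len(segs))
            pos += len(segs)
        for vid, segs in by_video.items():
            post = predict_posteriors(model, X_test[offsets[vid]])
            em = posteriors_to_emissions(
                post, model.classes, model.class_priors,
                mode=config.emission_mode, floor=config.emission_floor,
            )
            tl = viterbi(tm, em, video_id=vid)
            timelines.append(tl)
            smoothed.extend(tl.phases)
            truth = [s.phase for s in segs]
            _, disruptions = timeline_report(truth, tl.phases)
            vid_report = evaluate_predictions(truth, tl.phases)
            per_video[vid] = {
                "macro_f1": vid_report.macro_f1,
                "accuracy": vid_report.accuracy,
                "disruptions": disruptions,
                "n_segments": len(truth),
            }
        hmm_report = evaluate_predictions(y_test, smoothed)

    cv_report = None
    if config.cv_folds:
        cv_report = cross_validate(
            spec,
            config.feature,
            train,
            folds=config.cv_folds,
            seed=config.seed,
            preprocess_config=config.preprocess,
            balance=config.balance,
            smote_k=config.smote_k,
            feature_params=config.feature_params,
        )

    return ExperimentResult(
        config=config.resolved(),
        raw_report=raw_report,
        hmm_report=hmm_report,
        timelines=timelines,
        per_video=per_video,
        transition_model=tm,
        model=model,
        cv_report=cv_report,
    )


def _spec_kwargs(spec: ClassifierSpec) -> dict:
    return {f: getattr(spec, f) for f in spec.__dataclass_fields__}


def run_grid(
    corpus: Corpus,
    base: ExperimentConfig,
    features: Sequence[str] = FEATURE_NAMES,
    classifiers: Sequence[str] = CLASSIFIER_KINDS,
) -> pd.DataFrame:
    """The full comparison grid: every feature set x classifier kind,
    each scored with and without HMM coupling (4 x 4 x 2 = 32 rows)."""
    rows = []
    for feature in features:
        for kind in classifiers:
            cfg = ExperimentConfig(
                feature=feature,
                classifier=ClassifierSpec(
                    **{**_spec_kwargs(base.classifier), "kind": kind}
                ),
                preprocess=base.preprocess,
                test_video_ids=base.test_video_ids,
                feature_params=base.feature_params,
                balance=base.balance,
                balance_target=base.balance_target,
                smote_k=base.smote_k,
                hmm=True,
                hmm_alpha=base.hmm_alpha,
                emission_mode=base.emission_mode,
                emission_floor=base.emission_floor,
                extra_boost=base.extra_boost,
                seed=base.seed,
            )
            result = run_experiment(corpus, cfg)
            rows.append({
                "feature": feature, "classifier": kind, "hmm": False,
                "macro_f1": result.raw_report.macro_f1,
                "accuracy": result.raw_report.accuracy,
            })
            assert result.hmm_report is not None
            rows.append({
                "feature": feature, "classifier": kind, "hmm": True,
                "macro_f1": result.hmm_report.macro_f1,
                "accuracy": result.hmm_report.accuracy,
            })
    return pd.DataFrame(rows)
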