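"""Long-term-spectrum classifier baseline with its own winner-take-all stage.

The long-term spectrum of a call is summarized from its cochleagram as the
temporal variance of each channel's rate (one value per CF).  A linear
max-margin classifier (standardized predictors) is trained one-vs-rest per
category; the WTA stage compares signed decision values of the target and
distractor classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .calls import CallCorpus
from .cochleagram import Cochleagram, CochleagramParams, compute_cochleagram

__all__ = [
    "SpectrumFeature",
    "SpectrumClassifier",
    "long_term_spectrum",
    "train_spectrum_classifier",
    "spectrum_wta",
]


@dataclass
class SpectrumFeature:
    values: np.ndarray  # one value per channel
    cfs: np.ndarray
    source_call: str = ""


def long_term_spectrum(
    c: Cochleagram,
    mode: Literal["temporal_variance", "mean_rate"] = "temporal_variance",
) -> SpectrumFeature:
    """Per-channel long-term spectrum estimate from a cochleagram.

    ``temporal_variance`` (default) is the variance over time of each
    channel's rate; ``mean_rate`` returns the per-channel temporal mean
    (the alternative reading, selectable by flag).
    """
    if c.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate a long-term spectrum")
    if mode == "temporal_variance":
        vals = c.values.var(axis=1)
    elif mode == "mean_rate":
        vals = c.values.mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SpectrumFeature(values=vals, cfs=c.cfs.copy(), source_call=c.source_id)


@dataclass
class SpectrumClassifier:
    category: str
    pipeline: Pipeline
    cv_loss: float

    def decision_value(self, feat: SpectrumFeature) -> float:
        """Signed distance to the separating hyperplane."""
        return float(self.pipeline.decision_function(feat.values[None, :])[0])

    def to_json(self, path) -> None:
        scaler: StandardScaler = self.pipeline.named_steps["scale"]
        svm: SVC = self.pipeline.named_steps["svm"]
        w = (svm.coef_ if hasattr(svm, "coef_") else svm.dual_coef_ @ svm.support_vectors_)[0]
        payload = {
            "category": self.category,
            "cv_loss": self.cv_loss,
            "weights": w.tolist(),
            "bias": float(svm.intercept_[0]),
            "scale_mean": scaler.mean_.tolist(),
            "scale_std": scaler.scale_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def train_spectrum_classifier(
    features: Sequence[SpectrumFeature] | None = None,
    labels: Sequence[bool] | None = None,
    corpus: CallCorpus | None = None,
    category: str | None = None,
    params: CochleagramParams = CochleagramParams(),
    cochleagrams: dict[str, Cochleagram] | None = None,
    n_folds: int = 10,
    mode: Literal["temporal_variance", "mean_rate"] = "temporal_variance",
    seed: int = 0,
) -> SpectrumClassifier:
    """Linear-kernel SVM (standardized predictors) for one category vs rest,
    with k-fold cross-validated loss.

    Either pass precomputed ``features`` + boolean ``labels``, or a
    ``corpus`` + ``category`` (one-vs-many over the training split).
    """
    if features is None:
        if corpus is None or category is None:
            raise ValueError("need features+labels or corpus+category")
        train = corpus.subset(split="train")
        if cochleagrams is None:
            cochleagrams = {}
        feats, labs = [], []
        for call in train:
            if call.exemplar_id not in cochleagrams:
                cochleagrams[call.exemplar_id] = compute_cochleagram(call, params)
            feats.append(long_term_spectrum(cochleagrams[call.exemplar_id], mode=mode))
            labs.append(call.category == category)
        features, labels = feats, labs
    X = np.vstack([f.values for f in features])
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    if counts.min() < n_folds:
        raise ValueError(
            f"{n_folds}-fold CV needs >= {n_folds} calls per class (got {counts.min()})"
        )
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=1.0))]
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
    pipe.fit(X, y)
    return SpectrumClassifier(category=category or "", pipeline=pipe, cv_loss=float(1 - acc.mean()))


def spectrum_wta(
    target_clf: SpectrumClassifier,
    distractor_clf: SpectrumClassifier,
    feat: SpectrumFeature,
) -> str:
    """Go iff the target classifier's signed output exceeds the
    distractor's."""
    t = target_clf.decision_value(feat)
    d = distractor_clf.decision_value(feat)
    return "go" if t > d else "nogo"
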