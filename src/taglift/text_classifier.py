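"""Pluggable binary theme classifier.

The default model is a regularized log-linear (logistic) classifier over
token counts. Downstream stages consume only the prediction contract — a
probability in [0, 1] per text, thresholded at 0.5 (inclusive) — so any
object exposing ``predict_proba(texts) -> array`` (for example a wrapper
around a fine-tuned transformer) is interchangeable with the default model.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from .corpus_builder import Label, LabeledExample
from .errors import ContractViolationError, TrainingError

THRESHOLD = 0.5

# lowercase word characters plus apostrophes; '#' starts a hashtag token
_TOKEN_RE = re.compile(r"#[a-z0-9']+|[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on anything outside [a-z0-9#'].

    Tokens beginning with '#' are kept intact as hashtag tokens, and an
    embedded '#' starts a new hashtag token ("a#b" -> ["a", "#b"]).
    """
    return _TOKEN_RE.findall(text.lower())


class Call(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class PredictionRecord:
    item_id: str
    probability: float
    call: Call


@dataclass(frozen=True)
class TrainConfig:
    l2_strength: float = 1.0  # inverse of sklearn's C
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0


@dataclass
class ClassifierModel:
    """Token-count logistic model: p = sigmoid(intercept + sum_t w[t] n[t])."""

    vocabulary: dict[str, int]
    weights: np.ndarray
    intercept: float
    training_config: TrainConfig = field(default_factory=TrainConfig)

    def _count_matrix(self, texts) -> sparse.csr_matrix:
        indptr = [0]
        indices: list[int] = []
        data: list[int] = []
        vocab = self.vocabulary
        for text in texts:
            counts: dict[int, int] = {}
            for tok in tokenize(text):
                j = vocab.get(tok)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            indices.extend(counts.keys())
            data.extend(counts.values())
            indptr.append(len(indices))
        return sparse.csr_matrix(
            (np.asarray(data, dtype=float), np.asarray(indices, dtype=np.int64),
             np.asarray(indptr, dtype=np.int64)),
            shape=(len(indptr) - 1, len(vocab)))

    def predict_proba(self, texts) -> np.ndarray:
        """Probability of the positive class for each text; the empty text
        yields the intercept-only probability."""
        texts = list(texts)
        X = self._count_matrix(texts)
        logits = X @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))

    # ---- JSON serialization --------------------------------------------
    def save(self, path) -> None:
        payload = {
            "vocabulary": self.vocabulary,
            "weights": list(map(float, self.weights)),
            "intercept": float(self.intercept),
            "training_config": asdict(self.training_config),
        }
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with Path(path).open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            vocabulary=payload["vocabulary"],
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=payload["intercept"],
            training_config=TrainConfig(**payload["training_config"]),
        )


class ConstantClassifier:
    """Stub adapter emitting one fixed probability; useful for contract tests."""

    def __init__(self, probability: float):
        self.probability = probability

    def predict_proba(self, texts) -> np.ndarray:
        return np.full(len(list(texts)), self.probability, dtype=float)


def train_classifier(train: list[LabeledExample],
                     config: TrainConfig | None = None) -> ClassifierModel:
    """Fit the token-count logistic model. Deterministic given (data, config)."""
    config = config or TrainConfig()
    labels = {ex.label for ex in train}
    if labels != {Label.POSITIVE, Label.NEGATIVE}:
        raise TrainingError(
            f"training data must contain both classes, found {sorted(l.value for l in labels)}")
    vocab_tokens = sorted({tok for ex in train for tok in tokenize(ex.text)})
    vocabulary = {tok: j for j, tok in enumerate(vocab_tokens)}
    model = ClassifierModel(vocabulary=vocabulary,
                            weights=np.zeros(len(vocabulary)),
                            intercept=0.0, training_config=config)
    X = model._count_matrix([ex.text for ex in train])
    y = np.array([1 if ex.label is Label.POSITIVE else 0 for ex in train])
    clf = LogisticRegression(
        C=1.0 / config.l2_strength, solver="lbfgs", max_iter=config.max_iter,
        tol=config.tol, random_state=config.seed)
    clf.fit(X, y)
    model.weights = clf.coef_.ravel().astype(float)
    model.intercept = float(clf.intercept_[0])
    return model


def predict(model, texts, ids=None, threshold: float = THRESHOLD
            ) -> list[PredictionRecord]:
    """Apply any predict_proba-bearing model; validates the probability
    contract so misbehaving adapters fail loudly at the call site."""
    texts = list(texts)
    if ids is None:
        ids = [str(i) for i in range(len(texts))]
    ids = list(ids)
    if len(ids) != len(texts):
        raise ContractViolationError("ids and texts lengths differ")
    probs = np.asarray(model.predict_proba(texts), dtype=float)
    if probs.shape != (len(texts),):
        raise ContractViolationError(
            f"adapter returned shape {probs.shape}, expected ({len(texts)},)")
    if np.any(~np.isfinite(probs)) or np.any(probs < 0.0) or np.any(probs > 1.0):
        bad = probs[(~np.isfinite(probs)) | (probs < 0) | (probs > 1)][:3]
        raise ContractViolationError(
            f"adapter returned probabilities outside [0, 1]: {bad.tolist()}")
    return [
        PredictionRecord(item_id=i, probability=float(p),
                         call=Call.POSITIVE if p >= threshold else Call.NEGATIVE)
        for i, p in zip(ids, probs)
    ]


def accuracy(model, examples: list[LabeledExample],
             threshold: float = THRESHOLD) -> float:
    """Fraction of examples whose thresholded call matches the label."""
    records = predict(model, [ex.text for ex in examples], threshold=threshold)
    hits = sum(
        (r.call is Call.POSITIVE) == (ex.label is Label.POSITIVE)
        for r, ex in zip(records, examples))
    return hits / len(examples)
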