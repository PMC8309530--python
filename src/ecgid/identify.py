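"""NRC scoring, min-NRC identification, and evaluation metrics.

The Normalized Relative Compression of ``x`` against a reference ``y`` is
``NRC(x||y) = C(x||y) / |x|`` — near 0 when ``x`` is efficiently built from
``y``, near its maximum when the reference carries no information about
``x``.  Because the alphabet here has more than two symbols, the score is
additionally divided by ``log2 |A|`` so that coding under an empty model
saturates at exactly 1; the raw bits-per-symbol value is kept alongside.
Identification assigns a test segment to the reference subject whose model
yields the minimum NRC (the normalization constant cannot change the
argmin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fcm
from .errors import InvalidInputError
from .signal_prep import SymbolSequence

__all__ = [
    "NRCScore",
    "ReferenceSet",
    "MetricsReport",
    "nrc",
    "identify",
    "evaluate",
    "build_reference_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NRCScore:
    """NRC of a test segment against one reference subject.

    ``value`` is normalized to [0, ~1] (bits per symbol over ``log2 |A|``);
    ``bits_per_symbol`` is the raw C(x||y)/|x| of the defining formula.
    """

    value: float
    subject_id: str
    bits: float
    bits_per_symbol: float


@dataclass(frozen=True)
class ReferenceSet:
    """Per-subject reference models sharing order, alphabet and alpha policy."""

    models: dict[str, fcm.ContextModel]
    k: int
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise InvalidInputError("identification requires at least 2 reference subjects")
        for sid, model in self.models.items():
            if model.k != self.k or model.alphabet != self.alphabet:
                raise InvalidInputError(f"reference model {sid!r} has mismatched k or alphabet")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.models)


def build_reference_set(
    train_seqs: dict[str, SymbolSequence], k: int, alpha: fcm.AlphaSpec = "auto"
) -> ReferenceSet:
    """Train one frozen context model per subject from its training sequence."""
    if len(train_seqs) < 2:
        raise InvalidInputError("identification requires at least 2 reference subjects")
    models = {sid: fcm.train(seq, k, alpha) for sid, seq in train_seqs.items()}
    first = next(iter(models.values()))
    return ReferenceSet(models=models, k=k, alphabet=first.alphabet)


def nrc(
    x: SymbolSequence,
    model: fcm.ContextModel,
    subject_id: str = "",
    keys: fcm.SequenceKeys | None = None,
) -> NRCScore:
    """Normalized relative compression of ``x`` under a frozen reference model."""
    if len(x) < 1:
        raise InvalidInputError("cannot score an empty sequence")
    code = fcm.code_length(x, model, keys=keys)
    per_symbol = code.bits / code.n_symbols
    norm = np.log2(len(model.alphabet))
    return NRCScore(
        value=per_symbol / norm,
        subject_id=subject_id,
        bits=code.bits,
        bits_per_symbol=per_symbol,
    )


def identify(x: SymbolSequence, refs: ReferenceSet) -> tuple[str, list[NRCScore]]:
    """Attribute ``x`` to the reference subject with minimum NRC.

    Returns the winning subject id and the full score vector (sorted by
    subject id).  Exact ties resolve to the lexicographically smallest
    subject id, with a logged warning.
    """
    keys = fcm.SequenceKeys.of(x, refs.k)
    scores = [nrc(x, refs.models[sid], subject_id=sid, keys=keys) for sid in refs.subject_ids]
    best = min(s.value for s in scores)
    winners = [s.subject_id for s in scores if s.value == best]
    if len(winners) > 1:
        logger.warning(
            "NRC tie among %s; resolving to smallest subject id %r", winners, winners[0]
        )
    return winners[0], scores


@dataclass(frozen=True)
class MetricsReport:
    """Identification metrics from an N-class confusion matrix.

    Computed under the one-decision-per-subject protocol with macro
    one-vs-all averaging: sensitivity is the fraction of subjects correctly
    identified, error its complement, and accuracy/specificity/F1 are the
    macro means of the per-class binary quantities.
    """

    n_subjects: int
    accuracy: float
    error: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_subjects": self.n_subjects,
            "accuracy": self.accuracy,
            "error": self.error,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetricsReport":
        return cls(
            n_subjects=int(data["n_subjects"]),
            accuracy=float(data["accuracy"]),
            error=float(data["error"]),
            sensitivity=float(data["sensitivity"]),
            specificity=float(data["specificity"]),
            f1=float(data["f1"]),
            confusion=np.asarray(data["confusion"], dtype=np.int64),
            labels=tuple(data["labels"]),
        )


def evaluate(assignments: dict[str, str]) -> MetricsReport:
    """Score one identification decision per true subject.

    ``assignments`` maps each true subject id to the predicted subject id.
    With N subjects and one positive per class:

    - sensitivity SEN = (number correct) / N, error = 1 - SEN
    - macro accuracy  = mean_c (TP_c + TN_c) / N  = 1 - 2(1 - SEN)/N
    - macro specificity = mean_c TN_c / (N - 1)  = 1 - (1 - SEN)/(N - 1)
    - macro F1 = mean_c 2 TP_c / (2 TP_c + FP_c + FN_c)

    (the closed forms on the right hold because every class has exactly one
    positive decision; the implementation computes from the confusion
    matrix, which the closed forms cross-check).
    """
    if not assignments:
        raise InvalidInputError("no assignments to evaluate")
    labels = sorted(set(assignments) | set(assignments.values()))
    index = {lab: i for i, lab in enumerate(labels)}
    n_classes = len(labels)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for true, pred in assignments.items():
        confusion[index[true], index[pred]] += 1
    if confusion.sum(axis=1).max() > 1:
        raise InvalidInputError(
            "this evaluator expects exactly one decision per true subject; "
            "aggregate multi-segment decisions first"
        )
    n = len(assignments)  # decisions = true subjects
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    tn = n - tp - fp - fn
    sen = tp.sum() / n
    accuracy = float(np.mean((tp + tn) / n))
    specificity = float(np.mean(tn / (tn + fp)))
    f1 = float(np.mean(2 * tp / (2 * tp + fp + fn)))
    return MetricsReport(
        n_subjects=n,
        accuracy=accuracy,
        error=1.0 - sen,
        sensitivity=float(sen),
        specificity=specificity,
        f1=f1,
        confusion=confusion,
        labels=tuple(labels),
    )
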