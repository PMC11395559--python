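"""Quantitative readouts: per-offset masked accuracy, rank/probability
profiles, next-k-mer accuracy against the 4**-k random baseline, and binary
classification metrics including the Matthews correlation coefficient.

All functions here are pure: identical inputs give identical outputs, and no
global random state is consulted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from .datasets import MaskedSample, NextKmerDataset
from .tokenization import DataError, KmerVocabulary, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# masked-token readouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffsetAccuracyProfile:
    """Accuracy of masked-token prediction keyed by mask offset.

    ``overall`` is the count-weighted mean over offsets (equivalently over
    all masked positions); ``mean_over_samples`` first averages within each
    sample — both aggregations are reported because either reading of a
    whole-model accuracy is defensible.
    """

    per_offset: dict[int, float]
    counts: dict[int, int]
    overall: float
    mean_over_samples: float


def masked_accuracy_by_offset(
    profiles: Sequence[tuple[np.ndarray, MaskedSample]],
) -> OffsetAccuracyProfile:
    """Aggregate argmax correctness per mask offset relative to the chosen
    token.  Argmax ties break toward the lowest token id (counted, logged)."""
    if not profiles:
        raise DataError("no (prediction, sample) pairs supplied")
    ks = {s.k for _, s in profiles}
    offs = {s.offsets for _, s in profiles}
    if len(ks) > 1 or len(offs) > 1:
        raise ParameterError(f"mixed k or mask patterns in input: k={ks}, offsets={offs}")
    correct: dict[int, int] = {}
    counts: dict[int, int] = {}
    ties = 0
    sample_means = []
    for probs, sample in profiles:
        probs = np.asarray(probs)
        if probs.shape[0] != len(sample.masked_positions):
            raise ParameterError("prediction rows must match the number of masked positions")
        pred = probs.argmax(axis=1)
        ties += int((probs == probs.max(axis=1, keepdims=True)).sum() - probs.shape[0])
        hits = pred == np.asarray(sample.truth)
        for off, hit in zip(sample.offsets, hits):
            counts[off] = counts.get(off, 0) + 1
            correct[off] = correct.get(off, 0) + int(hit)
        sample_means.append(float(hits.mean()))
    if ties:
        logger.info("masked_accuracy_by_offset: %d argmax tie(s) broken toward lowest id", ties)
    per_offset = {off: correct[off] / counts[off] for off in sorted(counts)}
    total = sum(counts.values())
    overall = sum(correct.values()) / total
    return OffsetAccuracyProfile(
        per_offset=per_offset,
        counts=dict(sorted(counts.items())),
        overall=overall,
        mean_over_samples=float(np.mean(sample_means)),
    )


@dataclass(frozen=True)
class PositionRank:
    """Sorted prediction list for one masked position."""

    token_ids: np.ndarray  # sorted by descending probability, ties by id
    probabilities: np.ndarray  # non-increasing
    ranks: np.ndarray  # 1-based, aligned with token_ids
    truth_id: int
    truth_rank: int
    is_top1: bool
    n_above_floor: int


@dataclass(frozen=True)
class RankProfile:
    positions: tuple[PositionRank, ...]
    floor: float


def rank_probability_profile(
    probs: np.ndarray,
    sample: MaskedSample,
    vocab: KmerVocabulary,
    floor: float = 0.01,
) -> RankProfile:
    """Per-masked-position token ranking with a negligible-probability floor.

    Mirrors the per-mask probability readout: for each masked position the
    tokens sorted by predicted probability, the rank of the ground truth,
    and how many tokens exceed ``floor`` (a trained overlapping-token model
    concentrates essentially all mass on the 4 tokens consistent with the
    unmasked flanks).
    """
    probs = np.asarray(probs)
    if probs.shape != (len(sample.masked_positions), vocab.size):
        raise ParameterError(
            f"prediction matrix shape {probs.shape} != "
            f"({len(sample.masked_positions)}, {vocab.size})"
        )
    positions = []
    for row, truth in zip(probs, sample.truth):
        order = np.argsort(-row, kind="stable")  # ties -> lowest id first
        sorted_p = row[order]
        ranks = np.arange(1, len(row) + 1)
        truth_rank = int(np.nonzero(order == truth)[0][0]) + 1
        positions.append(
            PositionRank(
                token_ids=order,
                probabilities=sorted_p,
                ranks=ranks,
                truth_id=int(truth),
                truth_rank=truth_rank,
                is_top1=truth_rank == 1,
                n_above_floor=int((row > floor).sum()),
            )
        )
    return RankProfile(positions=tuple(positions), floor=floor)


# ---------------------------------------------------------------------------
# next-k-mer readouts
# ---------------------------------------------------------------------------


def random_baseline(k: int) -> float:
    """Accuracy of a uniform random guesser over the 4**k classes."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return 4.0**-k


def next_kmer_accuracy(classifier, dataset: NextKmerDataset) -> float:
    """Test-split accuracy of a fine-tuned next-k-mer classifier."""
    if not dataset.test_idx:
        raise DataError("dataset has an empty test split")
    n_classes = getattr(classifier, "n_classes", None)
    if n_classes is not None and n_classes != 4**dataset.k:
        raise ParameterError(
            f"classifier head has {n_classes} outputs but dataset k={dataset.k} "
            f"needs {4 ** dataset.k}"
        )
    test = dataset.test
    pred = np.asarray(classifier.predict([s.context for s in test]))
    true = np.asarray([s.label_class for s in test])
    return float((pred == true).mean())


# ---------------------------------------------------------------------------
# binary classification metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def classification_metrics(y_pred, y_true) -> MetricsReport:
    """Accuracy, precision, recall, F1 and MCC for binary labels.

    Zero-denominator cases (no predicted positives, single-class truth...)
    yield 0 for the affected metric, logged rather than raised.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape or y_pred.size == 0:
        raise ParameterError("label vectors must be equal-length and non-empty")
    labels = set(np.unique(y_pred)) | set(np.unique(y_true))
    if not labels <= {0, 1}:
        raise ParameterError(f"labels must be binary 0/1, got {sorted(labels)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero-division cases
        mcc = float(matthews_corrcoef(y_true, y_pred))
        report = MetricsReport(
            accuracy=float(accuracy_score(y_true, y_pred)),
            precision=float(precision_score(y_true, y_pred, zero_division=0)),
            recall=float(recall_score(y_true, y_pred, zero_division=0)),
            f1=float(f1_score(y_true, y_pred, zero_division=0)),
            mcc=mcc,
        )
    return report


def best_f1_threshold(p_real: np.ndarray, y_true: np.ndarray) -> tuple[float, MetricsReport]:
    """Diagnostic (non-default) readout: metrics at the F1-maximizing
    threshold over predicted probabilities."""
    p_real = np.asarray(p_real)
    y_true = np.asarray(y_true)
    best = (0.5, classification_metrics((p_real >= 0.5).astype(int), y_true))
    for t in np.unique(np.round(p_real, 6)):
        rep = classification_metrics((p_real >= t).astype(int), y_true)
        if rep.f1 > best[1].f1:
            best = (float(t), rep)
    return best


def write_report(path: str | Path, payload: dict) -> None:
    """JSON report plus a Markdown rendering beside it."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")
    md = ["# Evaluation report", ""]
    for key, value in payload.items():
        md.append(f"- **{key}**: `{json.dumps(value, default=_jsonify)}`")
    path.with_suffix(".md").write_text("\n".join(md) + "\n")


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    return str(x)
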