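"""Recall evaluation of the accelerated pipeline against the exhaustive
baseline: recall / missing-pair fraction, score distributions of all and
missing pairs, and per-sequence missing counts.

Pairs are matched by unordered id pair only; scores attached to missing
pairs are always the reference (oracle) scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .allvsall import PairSet

HISTOGRAM_BIN_WIDTH = 25.0


@dataclass
class RecallReport:
    n_reference: int
    n_predicted: int
    n_missing: int
    n_extra: int  # predicted pairs absent from the reference (precision violations)
    recall: float
    missing_fraction: float
    reference_scores: np.ndarray = field(repr=False)
    missing_scores: np.ndarray = field(repr=False)
    score_bin_edges: np.ndarray = field(repr=False)
    score_histogram_all: np.ndarray = field(repr=False)
    score_histogram_missing: np.ndarray = field(repr=False)
    per_sequence_missing: dict[str, int] = field(repr=False)
    empty_reference: bool = False

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_predicted": self.n_predicted,
            "n_missing": self.n_missing,
            "n_extra": self.n_extra,
            "recall": self.recall,
            "missing_fraction": self.missing_fraction,
            "score_bin_edges": self.score_bin_edges.tolist(),
            "score_histogram_all": self.score_histogram_all.tolist(),
            "score_histogram_missing": self.score_histogram_missing.tolist(),
            "per_sequence_missing": self.per_sequence_missing,
            "empty_reference": self.empty_reference,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _histogram(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per bin; the last bin is open to the right."""
    if len(edges) < 2:
        return np.zeros(0, dtype=int)
    clipped = np.minimum(scores, (edges[-2] + edges[-1]) / 2) if len(scores) else scores
    counts, _ = np.histogram(clipped, bins=edges)
    return counts


def evaluate_recall(
    predicted: PairSet, reference: PairSet, min_score: float = 135.75
) -> RecallReport:
    """recall = |predicted ∩ reference| / |reference|.

    Histograms are binned on reference scores in 25-unit bins starting at
    ``min_score`` (last bin open). An empty reference yields recall 1 by
    convention, with a warning and the ``empty_reference`` flag set.
    """
    ref_keys = reference.keys()
    pred_keys = predicted.keys()
    inter = ref_keys & pred_keys
    missing_keys = ref_keys - pred_keys
    n_extra = len(pred_keys - ref_keys)
    n_ref = len(ref_keys)
    ref_scores = np.array(sorted(p.score for p in reference), dtype=float)
    missing_scores = np.array(
        sorted(reference.get(*k).score for k in missing_keys), dtype=float
    )
    if n_ref == 0:
        warnings.warn("empty reference PairSet: recall set to 1 by convention")
        recall = 1.0
    else:
        recall = len(inter) / n_ref
    hi = max(ref_scores.max(), min_score + HISTOGRAM_BIN_WIDTH) if n_ref else min_score
    n_bins = int(np.ceil((hi - min_score) / HISTOGRAM_BIN_WIDTH)) + 1
    edges = min_score + HISTOGRAM_BIN_WIDTH * np.arange(n_bins + 1)
    per_seq: dict[str, int] = {}
    for a, b in missing_keys:
        per_seq[a] = per_seq.get(a, 0) + 1
        per_seq[b] = per_seq.get(b, 0) + 1
    return RecallReport(
        n_reference=n_ref,
        n_predicted=len(pred_keys),
        n_missing=len(missing_keys),
        n_extra=n_extra,
        recall=recall,
        missing_fraction=1.0 - recall,
        reference_scores=ref_scores,
        missing_scores=missing_scores,
        score_bin_edges=edges,
        score_histogram_all=_histogram(ref_scores, edges),
        score_histogram_missing=_histogram(missing_scores, edges),
        per_sequence_missing=per_seq,
        empty_reference=(n_ref == 0),
    )


@dataclass(frozen=True)
class SkewStatistic:
    median_missing: float
    median_all: float

    @property
    def ratio(self) -> float:
        return self.median_missing / self.median_all


def missing_score_skew(report: RecallReport) -> SkewStatistic | None:
    """Median oracle score of missing pairs vs of all reference pairs.

    A ratio < 1 indicates the missed pairs concentrate at low scores.
    Returns None when nothing is missing.
    """
    if report.n_missing == 0:
        return None
    return SkewStatistic(
        float(np.median(report.missing_scores)),
        float(np.median(report.reference_scores)),
    )
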