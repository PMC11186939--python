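"""Clip → view → subject aggregation by majority voting.

Clip-level predictions are reduced to a view-level label by majority vote;
the view-level confidence C = y*/n is the fraction of clips agreeing with
the winner. Subject-level labels majority-vote the available views; view
ties resolve toward the tied label backed by the single most confident view,
and any residual exact tie resolves toward the higher severity (clinically
conservative: prefer flagging disease).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import ValidationError

__all__ = [
    "PredictionBundle",
    "SubjectPrediction",
    "majority_vote",
    "aggregate_view",
    "aggregate_subject",
]


def majority_vote(labels: Sequence[int]) -> tuple[int, int]:
    """Modal label and its multiplicity; modal ties break toward higher
    severity."""
    labels = list(labels)
    if not labels:
        raise ValidationError("cannot vote over an empty label list")
    values, counts = np.unique(np.asarray(labels, dtype=int), return_counts=True)
    top = counts.max()
    winner = int(values[counts == top].max())
    return winner, int(top)


@dataclass
class PredictionBundle:
    """One view's clip predictions and their majority-vote summary."""

    clip_labels: list[int]
    clip_probabilities: Optional[np.ndarray] = None  # (n, num_classes)
    view: str = ""
    subject_id: str = ""
    label: int = field(init=False)
    modal_count: int = field(init=False)
    confidence: float = field(init=False)

    def __post_init__(self) -> None:
        self.label, self.modal_count = majority_vote(self.clip_labels)
        self.confidence = self.modal_count / len(self.clip_labels)

    @property
    def n(self) -> int:
        return len(self.clip_labels)

    def mean_probabilities(self) -> Optional[np.ndarray]:
        if self.clip_probabilities is None:
            return None
        return np.asarray(self.clip_probabilities).mean(axis=0)


def aggregate_view(
    clip_labels: Sequence[int],
    clip_probabilities: Optional[np.ndarray] = None,
    view: str = "",
    subject_id: str = "",
) -> PredictionBundle:
    """Majority-vote n clip predictions into a view-level bundle with
    confidence C = y*/n."""
    return PredictionBundle(
        clip_labels=list(clip_labels),
        clip_probabilities=clip_probabilities,
        view=view,
        subject_id=subject_id,
    )


@dataclass
class SubjectPrediction:
    """Final subject-level call with its provenance."""

    label: int
    winning_view: str
    confidence: float
    view_bundles: Mapping[str, PredictionBundle]

    @property
    def winning_probabilities(self) -> Optional[np.ndarray]:
        """Mean clip probabilities of the most confident supporting view —
        the probabilities used for multi-view AUROC."""
        return self.view_bundles[self.winning_view].mean_probabilities()


def aggregate_subject(
    view_bundles: Mapping[str, PredictionBundle] | Sequence[PredictionBundle],
) -> SubjectPrediction:
    """Majority vote over view-level predictions.

    On a vote tie the tied label whose supporting views contain the single
    highest confidence wins; exact confidence ties resolve toward higher
    severity. Missing views are simply absent from the vote.
    """
    if not isinstance(view_bundles, Mapping):
        view_bundles = {b.view or str(i): b for i, b in enumerate(view_bundles)}
    if not view_bundles:
        raise ValidationError("no view predictions to aggregate")
    labels = np.array([b.label for b in view_bundles.values()])
    values, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = values[counts == top]
    if len(tied) == 1:
        winner = int(tied[0])
    else:
        # (max supporter confidence, severity) lexicographic tie-break
        best = max(
            (
                max(b.confidence for b in view_bundles.values() if b.label == lab),
                lab,
            )
            for lab in tied
        )
        winner = int(best[1])
    supporters = {k: b for k, b in view_bundles.items() if b.label == winner}
    win_key = max(supporters, key=lambda k: supporters[k].confidence)
    return SubjectPrediction(
        label=winner,
        winning_view=win_key,
        confidence=supporters[win_key].confidence,
        view_bundles=dict(view_bundles),
    )
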