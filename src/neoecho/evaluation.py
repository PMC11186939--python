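"""Patient-level splitting and the classification metric suite.

Model selection uses repeated stratified splitting (Monte-Carlo
cross-validation): the cohort is split ten times into 80% training / 20%
validation *on a subject basis*, stratified by severity, so no subject ever
contributes recordings to both sides of a split. True k-fold partitioning is
available as an option. Metrics: one-vs-one AUROC, balanced accuracy
(mean per-class recall), frequency-weighted F1/precision/recall, and the
mean view-level confidence; per-repetition values are summarized as
mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .types import ValidationError

__all__ = [
    "SplitPlan",
    "repeated_stratified_splits",
    "kfold_splits",
    "compute_metrics",
    "summarize_folds",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "auroc",
    "balanced_accuracy",
    "f1",
    "precision",
    "recall",
    "confidence",
)


@dataclass
class SplitPlan:
    """Per-repetition train/validation subject-id sets."""

    repetitions: list[tuple[set, set]]
    val_fraction: float
    seed: int

    def __iter__(self):
        return iter(self.repetitions)

    def __len__(self) -> int:
        return len(self.repetitions)

    def check_disjoint(self) -> bool:
        return all(not (tr & va) for tr, va in self.repetitions)


def _validate_subject_labels(subjects: Mapping[str, int]) -> dict[int, list[str]]:
    if not subjects:
        raise ValidationError("no subjects to split")
    by_class: dict[int, list[str]] = {}
    for sid, lab in subjects.items():
        by_class.setdefault(int(lab), []).append(sid)
    for lab, ids in by_class.items():
        if len(ids) < 2:
            raise ValidationError(
                f"class {lab} has a single subject; stratified splitting impossible"
            )
        ids.sort()
    return by_class


def repeated_stratified_splits(
    subjects: Mapping[str, int],
    repetitions: int = 10,
    val_fraction: float = 0.20,
    seed: int = 0,
) -> SplitPlan:
    """Independent stratified subject-level train/validation splits.

    Within each repetition every class contributes ``round(val_fraction ·
    class size)`` subjects (at least one) to validation; train and validation
    partition the cohort. Deterministic given seed.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValidationError(f"val_fraction must be in (0, 1), got {val_fraction}")
    by_class = _validate_subject_labels(subjects)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(repetitions):
        train: set = set()
        val: set = set()
        for lab in sorted(by_class):
            ids = np.array(by_class[lab])
            n_val = min(len(ids) - 1, max(1, int(round(val_fraction * len(ids)))))
            perm = rng.permutation(len(ids))
            val.update(ids[perm[:n_val]])
            train.update(ids[perm[n_val:]])
        reps.append((train, val))
    return SplitPlan(repetitions=reps, val_fraction=val_fraction, seed=seed)


def kfold_splits(subjects: Mapping[str, int], k: int = 5, seed: int = 0) -> SplitPlan:
    """True stratified k-fold partition at the subject level."""
    by_class = _validate_subject_labels(subjects)
    rng = np.random.default_rng(seed)
    folds: list[set] = [set() for _ in range(k)]
    for lab in sorted(by_class):
        ids = np.array(by_class[lab])
        perm = rng.permutation(len(ids))
        for i, j in enumerate(perm):
            folds[i % k].add(ids[j])
    all_ids = set(subjects)
    reps = [(all_ids - f, f) for f in folds]
    return SplitPlan(repetitions=reps, val_fraction=1.0 / k, seed=seed)


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    y_prob: Optional[np.ndarray] = None,
    confidences: Optional[Sequence[float]] = None,
    num_classes: Optional[int] = None,
) -> dict[str, float]:
    """One repetition's metric entry.

    AUROC is one-vs-one over the classes present in the truth; with a
    single-class truth it is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must be nonempty and aligned")
    present = np.unique(y_true)
    out: dict[str, float] = {}
    if y_prob is not None and len(present) >= 2:
        y_prob = np.asarray(y_prob, dtype=float)
        if len(present) == 2:
            # binarized: score of the larger class among those present
            pos = int(present.max())
            out["auroc"] = float(
                _skm.roc_auc_score((y_true == pos).astype(int), y_prob[:, pos])
            )
        else:
            # renormalize over present classes for ovo averaging
            sub = y_prob[:, present]
            sub = sub / sub.sum(axis=1, keepdims=True)
            out["auroc"] = float(
                _skm.roc_auc_score(y_true, sub, multi_class="ovo", labels=present)
            )
    else:
        out["auroc"] = float("nan")
    out["balanced_accuracy"] = float(_skm.balanced_accuracy_score(y_true, y_pred))
    out["f1"] = float(_skm.f1_score(y_true, y_pred, average="weighted", zero_division=0))
    out["precision"] = float(
        _skm.precision_score(y_true, y_pred, average="weighted", zero_division=0)
    )
    out["recall"] = float(
        _skm.recall_score(y_true, y_pred, average="weighted", zero_division=0)
    )
    out["confidence"] = (
        float(np.mean(confidences)) if confidences is not None else float("nan")
    )
    return out


def summarize_folds(entries: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Mean and sample SD per metric over repetitions.

    A single entry reports SD 0 by convention.
    """
    if not entries:
        raise ValidationError("no metric entries to summarize")
    frame = pd.DataFrame(list(entries))
    mean = frame.mean()
    sd = frame.std(ddof=1).fillna(0.0) if len(frame) > 1 else mean * 0.0
    return pd.DataFrame({"mean": mean, "sd": sd})
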