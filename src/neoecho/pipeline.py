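"""End-to-end drivers: synthetic-cohort experiments, training and scoring.

These functions wire the modules together the way the full-scale study runs:
render (or load) recordings, extract clips, train a per-view classifier with
balanced resampling and augmentation, aggregate clip predictions to view and
subject level, and score patient-level metrics on held-out subjects. The
synthetic experiments are the desk-scale stand-ins for the clinical
experiments: 64×64 phantom loops and a reduced-width 3D backbone keep a full
train/evaluate cycle in CPU minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aggregate import PredictionBundle, aggregate_subject, aggregate_view
from .augment import AugmentConfig
from .classifiers import (
    EchoClassifier,
    TrainConfig,
    build_model,
    predict,
    train_classifier,
)
from .clips import ClipSpec, extract_clips
from .evaluation import compute_metrics, repeated_stratified_splits
from .io import CohortManifest, read_echo_video
from .synth import SynthConfig, SynthResult, default_class_counts, render_subject
from .types import EchoVideo, View

__all__ = [
    "SubjectRecord",
    "simulate_cohort",
    "predict_recording",
    "train_view_classifier",
    "evaluate_view",
    "run_single_view_experiment",
    "run_multi_view_experiment",
]


@dataclass
class SubjectRecord:
    """One simulated subject: severity label plus per-view renders."""

    subject_id: str
    label: int
    views: dict[str, SynthResult] = field(default_factory=dict)


def simulate_cohort(
    n_subjects: int,
    views: Sequence[View | str] = (View.PSAX_P,),
    class_counts: Optional[Sequence[int]] = None,
    seed: int = 0,
    T: int = 122,
    H: int = 64,
    W: int = 64,
    speckle_strength: float = 0.15,
) -> list[SubjectRecord]:
    """In-memory cohort with per-subject anatomical jitter.

    Class counts default to the 65/17/18% prevalence of the emulated cohort.
    """
    if class_counts is None:
        class_counts = default_class_counts(n_subjects)
    views = [View.parse(v) for v in views]
    labels = np.repeat([0, 1, 2], class_counts)
    root = np.random.SeedSequence(seed)
    records = []
    for idx, label in enumerate(labels):
        sub_rng = np.random.default_rng(root.spawn(1)[0])
        rec = SubjectRecord(subject_id=f"S{idx:04d}", label=int(label))
        scale = sub_rng.uniform(0.9, 1.1)
        rot = sub_rng.uniform(-5.0, 5.0)
        brightness = sub_rng.uniform(0.9, 1.1)
        length = T + int(sub_rng.integers(-2, 3))
        for view in views:
            cfg = SynthConfig(
                T=length, H=H, W=W, severity=int(label),
                speckle_strength=speckle_strength, brightness=brightness,
                scale=scale, extra_rotation=rot,
                seed=int(sub_rng.integers(0, 2**31 - 1)),
            )
            result = render_subject(cfg, view)
            result.video.subject_id = rec.subject_id
            rec.views[view.value] = result
        records.append(rec)
    return records


def predict_recording(
    classifier: EchoClassifier,
    video: EchoVideo,
    spec: ClipSpec,
    rng: np.random.Generator,
) -> PredictionBundle:
    """n random clips → clip predictions → view-level majority vote."""
    clips = extract_clips(video, spec, rng)
    probs, labels = predict(classifier, [c.frames for c in clips])
    return aggregate_view(
        labels.tolist(), probs, view=video.view.value, subject_id=video.subject_id
    )


def train_view_classifier(
    videos: Sequence[EchoVideo],
    labels: Sequence[int],
    spec: ClipSpec,
    epochs: int,
    seed: int,
    variant: str = "tiny_3d",
    num_classes: int = 3,
    mean: float = 0.45,
    std: float = 0.25,
    augment: Optional[AugmentConfig] = None,
) -> tuple[EchoClassifier, dict]:
    """Train one view's clip classifier from labeled recordings."""
    rng = np.random.default_rng(seed)
    samples = []
    for video, lab in zip(videos, labels):
        for clip in extract_clips(video, spec, rng):
            samples.append((clip.frames, int(lab)))
    clf = build_model(variant, num_classes=num_classes, mean=mean, std=std, seed=seed)
    cfg = TrainConfig(epochs=epochs, num_classes=num_classes, seed=seed)
    history = train_classifier(clf, samples, cfg, augment=augment, rng=rng)
    return clf, history


def evaluate_view(
    classifier: EchoClassifier,
    videos: Sequence[EchoVideo],
    labels: Sequence[int],
    spec: ClipSpec,
    rng: np.random.Generator,
) -> tuple[dict, list[PredictionBundle]]:
    """Subject-level metrics of a single-view model on held-out recordings."""
    bundles = [predict_recording(classifier, v, spec, rng) for v in videos]
    y_pred = [b.label for b in bundles]
    y_prob = np.stack([b.mean_probabilities() for b in bundles])
    conf = [b.confidence for b in bundles]
    metrics = compute_metrics(labels, y_pred, y_prob, confidences=conf)
    return metrics, bundles


# Desk-scale training schedule: clips per training recording and epochs are
# sized so a full experiment stays in CPU minutes; evaluation always uses
# the study's n=10 clips per recording.
_TRAIN_CLIPS = 6
_EVAL_SPEC = ClipSpec(n=10, k=12, s=1)


def run_single_view_experiment(
    seed: int = 0,
    n_subjects: int = 120,
    view: View | str = View.PSAX_P,
    epochs: int = 6,
    val_fraction: float = 0.2,
    augment: bool = True,
    T: int = 122,
    H: int = 64,
    W: int = 64,
) -> dict:
    """Synthetic recovery experiment: train a tiny 3D classifier on one view
    of a simulated cohort and score held-out subjects.

    Returns metrics, the trained classifier, the evaluation bundles and the
    train/validation subject split.
    """
    view = View.parse(view)
    records = simulate_cohort(n_subjects, views=[view], seed=seed, T=T, H=H, W=W)
    subjects = {r.subject_id: r.label for r in records}
    plan = repeated_stratified_splits(subjects, repetitions=1,
                                      val_fraction=val_fraction, seed=seed + 1)
    train_ids, val_ids = plan.repetitions[0]
    by_id = {r.subject_id: r for r in records}
    train_recs = [by_id[s] for s in sorted(train_ids)]
    val_recs = [by_id[s] for s in sorted(val_ids)]
    train_spec = ClipSpec(n=_TRAIN_CLIPS, k=_EVAL_SPEC.k, s=_EVAL_SPEC.s)
    clf, history = train_view_classifier(
        [r.views[view.value].video for r in train_recs],
        [r.label for r in train_recs],
        train_spec,
        epochs=epochs,
        seed=seed + 2,
        augment=AugmentConfig() if augment else None,
    )
    eval_rng = np.random.default_rng(seed + 3)
    metrics, bundles = evaluate_view(
        clf,
        [r.views[view.value].video for r in val_recs],
        [r.label for r in val_recs],
        _EVAL_SPEC,
        eval_rng,
    )
    return dict(
        metrics=metrics,
        history=history,
        classifier=clf,
        bundles=bundles,
        train_ids=sorted(train_ids),
        val_ids=sorted(val_ids),
        records=by_id,
        view=view.value,
    )


def run_multi_view_experiment(
    seed: int = 0,
    n_subjects: int = 60,
    views: Sequence[View | str] = (View.PSAX_P, View.PLAX, View.A4C),
    epochs: int = 4,
    val_fraction: float = 0.2,
    augment: bool = True,
    T: int = 122,
    H: int = 64,
    W: int = 64,
) -> dict:
    """Multi-view voting experiment over one strong and two weaker views.

    Trains one classifier per view, votes view-level predictions per subject
    (confidence tie-break), and reports per-view and multi-view balanced
    accuracies on the held-out subjects.
    """
    views = [View.parse(v) for v in views]
    records = simulate_cohort(n_subjects, views=views, seed=seed, T=T, H=H, W=W)
    subjects = {r.subject_id: r.label for r in records}
    plan = repeated_stratified_splits(subjects, repetitions=1,
                                      val_fraction=val_fraction, seed=seed + 1)
    train_ids, val_ids = plan.repetitions[0]
    by_id = {r.subject_id: r for r in records}
    train_recs = [by_id[s] for s in sorted(train_ids)]
    val_recs = [by_id[s] for s in sorted(val_ids)]
    train_spec = ClipSpec(n=_TRAIN_CLIPS, k=_EVAL_SPEC.k, s=_EVAL_SPEC.s)

    per_view_metrics: dict[str, dict] = {}
    per_view_bundles: dict[str, list[PredictionBundle]] = {}
    for vi, view in enumerate(views):
        clf, _ = train_view_classifier(
            [r.views[view.value].video for r in train_recs],
            [r.label for r in train_recs],
            train_spec,
            epochs=epochs,
            seed=seed + 10 + vi,
            augment=AugmentConfig() if augment else None,
        )
        eval_rng = np.random.default_rng(seed + 100 + vi)
        metrics, bundles = evaluate_view(
            clf,
            [r.views[view.value].video for r in val_recs],
            [r.label for r in val_recs],
            _EVAL_SPEC,
            eval_rng,
        )
        per_view_metrics[view.value] = metrics
        per_view_bundles[view.value] = bundles

    y_true, y_pred, y_prob, confidences = [], [], [], []
    for i, rec in enumerate(val_recs):
        bundles = {v.value: per_view_bundles[v.value][i] for v in views}
        sub = aggregate_subject(bundles)
        y_true.append(rec.label)
        y_pred.append(sub.label)
        y_prob.append(sub.winning_probabilities)
        confidences.append(sub.confidence)
    multi = compute_metrics(y_true, y_pred, np.stack(y_prob), confidences=confidences)
    return dict(
        per_view_metrics=per_view_metrics,
        multi_view_metrics=multi,
        val_ids=sorted(val_ids),
        views=[v.value for v in views],
    )


def load_manifest_videos(
    manifest: CohortManifest, view: View | str
) -> tuple[list[EchoVideo], list[int]]:
    """Load one view's labeled recordings from a manifest."""
    sub = manifest.for_view(view)
    videos, labels = [], []
    for row in sub.rows():
        video = read_echo_video(row["path"], view=row["view"],
                                subject_id=row["subject_id"], label=row["label"])
        videos.append(video)
        labels.append(int(row["label"]))
    return videos, labels
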