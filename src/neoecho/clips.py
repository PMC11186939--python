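"""Frame and clip selection.

Two frame-selection routes feed the spatial classifier: uniform random
frames, and cardiac-phase selection from segmentation masks — the per-frame
relative ventricle area is minimal at systole (when septal morphology is most
informative for PH grading) and maximal at diastole, so the extreme tails of
the area trace identify the phases of interest. The spatio-temporal
classifier instead consumes k-frame clips sampled at interval s (effective
length l = k·s), with n clips per recording drawn at random start frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EchoVideo, MaskSequence, ValidationError

__all__ = [
    "ClipSpec",
    "Clip",
    "relative_ventricle_area",
    "select_extreme_frames",
    "select_random_frames",
    "extract_clips",
]


@dataclass(frozen=True)
class ClipSpec:
    """Clip sampling parameters: n clips per recording, k frames per clip,
    sampling interval s. Defaults n=10, k=12, s=1 — a 12-frame clip covers at
    least one neonatal heartbeat (~10 frames at 25 fps)."""

    n: int = 10
    k: int = 12
    s: int = 1

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1 or self.s < 1:
            raise ValidationError(f"n, k, s must all be >= 1; got {self}")

    @property
    def effective_length(self) -> int:
        """Number of parent-video frames a clip spans: l = k·s."""
        return self.k * self.s

    def min_video_length(self) -> int:
        return (self.k - 1) * self.s + 1


@dataclass
class Clip:
    """A k-frame subsequence of one recording, sampled at interval s."""

    frames: np.ndarray
    start: int
    spec: ClipSpec
    subject_id: str
    view: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.spec.k:
            raise ValidationError(
                f"clip has {self.frames.shape[0]} frames, spec says k={self.spec.k}"
            )

    @property
    def frame_indices(self) -> np.ndarray:
        """Parent-video indices: start + i·s for i in [0, k)."""
        return self.start + np.arange(self.spec.k) * self.spec.s


def relative_ventricle_area(masks: MaskSequence | np.ndarray) -> np.ndarray:
    """Per-frame fraction of ventricle (LV ∪ RV) pixels in [0, 1]."""
    arr = masks.masks if isinstance(masks, MaskSequence) else np.asarray(masks)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValidationError(f"expected nonempty (T,H,W) mask stack, got {arr.shape}")
    t, h, w = arr.shape
    return arr.reshape(t, -1).sum(axis=1) / float(h * w)


def select_extreme_frames(
    areas: np.ndarray, mode: str = "min", fraction: float = 0.10
) -> np.ndarray:
    """Indices of the ⌈fraction·T⌉ frames with the smallest (``mode='min'``,
    systole) or largest (``'max'``, diastole) relative ventricle area.

    Ties break toward the earlier frame; the result is sorted ascending.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.ndim != 1 or areas.size == 0:
        raise ValidationError("areas must be a nonempty 1-D array")
    if mode not in ("min", "max"):
        raise ValidationError(f"mode must be 'min' or 'max', got {mode!r}")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n_take = int(np.ceil(fraction * areas.size))
    key = areas if mode == "min" else -areas
    # stable sort => ties resolve toward the lower frame index
    order = np.argsort(key, kind="stable")
    return np.sort(order[:n_take])


def select_random_frames(
    video: EchoVideo, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n distinct frame indices drawn uniformly without replacement."""
    t = video.n_frames
    if n > t:
        raise ValidationError(f"cannot draw {n} distinct frames from {t}")
    return rng.choice(t, size=n, replace=False)


def extract_clips(
    video: EchoVideo, spec: ClipSpec, rng: np.random.Generator
) -> list[Clip]:
    """Draw ``spec.n`` clips with uniformly random start frames.

    Starts are drawn independently (overlaps allowed — n·k may exceed T).
    Raises if the recording is shorter than the (k−1)·s+1 frames a single
    clip needs.
    """
    t = video.n_frames
    need = spec.min_video_length()
    if t < need:
        raise ValidationError(
            f"video of {t} frames too short for k={spec.k}, s={spec.s}; "
            f"needs at least {need} frames"
        )
    max_start = t - (spec.k - 1) * spec.s - 1
    starts = rng.integers(0, max_start + 1, size=spec.n)
    clips = []
    for start in starts:
        idx = int(start) + np.arange(spec.k) * spec.s
        clips.append(
            Clip(
                frames=video.frames[idx].copy(),
                start=int(start),
                spec=spec,
                subject_id=video.subject_id,
                view=video.view.value,
                label=video.label,
            )
        )
    return clips
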