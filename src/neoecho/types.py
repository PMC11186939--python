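"""Core domain types for neonatal echocardiogram analysis.

The package works on grayscale 2D echocardiography (ECHO) video loops, one per
standard transducer view, graded on a three-level pulmonary-hypertension (PH)
scale: 0 = no PH, 1 = mild PH (septal flattening), 2 = moderate-to-severe PH
(septum bowing into the left ventricle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "View",
    "SEVERITY_LEVELS",
    "EchoVideo",
    "MaskSequence",
    "ClinicalMeasures",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected container."""


class View(str, Enum):
    """The five standard neonatal echo views.

    PSAX-P (parasternal short axis at the papillary-muscle level) is the view
    on which septal morphology — and hence PH grading — is most visible.
    """

    PSAX_P = "PSAX-P"
    PLAX = "PLAX"
    A4C = "A4C"
    PSAX_S = "PSAX-S"
    PSAX_A = "PSAX-A"

    @classmethod
    def parse(cls, value: "View | str") -> "View":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            valid = ", ".join(v.value for v in cls)
            raise ValidationError(
                f"unknown view {value!r}; expected one of: {valid}"
            ) from None


#: Valid severity labels: 0 = none, 1 = mild, 2 = moderate-to-severe.
SEVERITY_LEVELS = (0, 1, 2)


@dataclass
class EchoVideo:
    """One view's grayscale frame stack with subject metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` uint8 stack of intensities in [0, 255].
    fps
        Frame rate in frames per second; must be positive.
    view
        One of the five standard views.
    subject_id
        Opaque subject identifier.
    label
        Optional PH severity in {0, 1, 2}.
    """

    frames: np.ndarray
    fps: float
    view: View
    subject_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be (T, H, W); got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if t < 1:
            raise ValidationError("video must contain at least one frame")
        if h < 8 or w < 8:
            raise ValidationError(f"frame size {h}x{w} below 8x8 minimum")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValidationError("intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        self.view = View.parse(self.view)
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in SEVERITY_LEVELS:
                raise ValidationError(
                    f"label must be in {SEVERITY_LEVELS}, got {self.label}"
                )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.n_frames / self.fps

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EchoVideo):
            return NotImplemented
        return (
            np.array_equal(self.frames, other.frames)
            and self.fps == other.fps
            and self.view == other.view
            and self.subject_id == other.subject_id
            and self.label == other.label
        )


@dataclass
class MaskSequence:
    """Per-frame binary ventricle masks (1 = LV ∪ RV pixel).

    ``source`` records whether masks came from an external segmentation model
    or from the synthetic simulator's ground truth.
    """

    masks: np.ndarray
    source: str = "external"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValidationError(
                f"masks must be (T, H, W); got shape {self.masks.shape}"
            )
        uniq = np.unique(self.masks)
        if not np.isin(uniq, [0, 1]).all():
            raise ValidationError("mask values must be 0 or 1")
        self.masks = self.masks.astype(np.uint8)
        if self.source not in ("external", "synthetic"):
            raise ValidationError(
                f"source must be 'external' or 'synthetic', got {self.source!r}"
            )

    def matches(self, video: EchoVideo) -> bool:
        return self.masks.shape == video.frames.shape


@dataclass
class ClinicalMeasures:
    """Doppler-derived pressure quantities used in clinical PH screening.

    TRV is the tricuspid regurgitation jet velocity (m/s), RAP the right
    atrial pressure (mmHg); sPAP/mPAP are the systolic and mean pulmonary
    artery pressures (mmHg) estimated from them.
    """

    trv: float
    rap: float
    spap: Optional[float] = None
    mpap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trv < 0:
            raise ValidationError(f"TRV must be >= 0 m/s, got {self.trv}")
        if self.rap < 0:
            raise ValidationError(f"RAP must be >= 0 mmHg, got {self.rap}")
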