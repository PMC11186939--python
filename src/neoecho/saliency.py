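"""Gradient-weighted class activation mapping for spatio-temporal models.

Grad-CAM assigns each unit of a late convolutional layer a relevance weight
for a target class — the spatio-temporal mean of the class logit's gradient
with respect to that channel's activation — and combines channels into a
ReLU-rectified relevance map. Extended to 3D inputs, the map localizes the
video regions (in space *and* time) the model found most informative; it is
upsampled trilinearly to the clip's resolution and min-max normalized per
volume, preserving temporal emphasis. A weight-randomization check guards
against saliency that merely edge-detects the input.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _stats
from skimage.transform import resize as _sk_resize

from .classifiers import EchoClassifier
from .types import ValidationError

__all__ = [
    "SaliencyVolume",
    "gradcam3d",
    "render_overlay",
    "randomization_sanity",
]


@dataclass
class SaliencyVolume:
    """Nonnegative spatio-temporal relevance map aligned to a clip.

    ``map`` is normalized to [0, 1] at the clip's (k, H, W) resolution;
    ``raw`` keeps the pre-normalization coarse map (useful for equivariance
    checks); an all-zero map is the degenerate no-evidence case.
    """

    map: np.ndarray
    target_class: int
    layer: str
    raw: np.ndarray

    def __post_init__(self) -> None:
        if (self.map < 0).any() or (self.map > 1).any():
            raise ValidationError("saliency map must lie in [0, 1]")


def gradcam3d(
    classifier: EchoClassifier,
    clip: np.ndarray,
    target_class: int,
    layer: Optional[str] = None,
) -> SaliencyVolume:
    """Compute the Grad-CAM volume of ``clip`` for ``target_class``.

    ``layer`` defaults to the model's last convolutional block. The channel
    weights are α_c = mean_(t,h,w) ∂y_target/∂A_c; the coarse map
    ReLU(Σ_c α_c A_c) is trilinearly upsampled to the clip shape and min-max
    normalized (a constant map maps to all zeros).
    """
    layer = layer or classifier.last_conv_stage
    model = classifier.model
    model.capture(layer)  # raises on unknown layer
    clip = np.asarray(clip)
    if clip.ndim != 3:
        raise ValidationError(f"expected a (k, H, W) clip, got shape {clip.shape}")
    model.set_training(False)
    logits = model(classifier.prepare_batch([clip]))
    if not 0 <= target_class < logits.shape[1]:
        raise ValidationError(
            f"target_class {target_class} outside [0, {logits.shape[1]})"
        )
    gout = np.zeros_like(logits)
    gout[0, target_class] = 1.0
    for p in model.parameters():
        p.zero_grad()
    model.backward(gout)
    acts = model.activations[layer][0]      # (C, T', H', W')
    grads = model.gradients[layer][0]
    alpha = grads.mean(axis=(1, 2, 3))      # channel weights
    coarse = np.maximum(np.tensordot(alpha, acts, axes=([0], [0])), 0.0)
    raw = _sk_resize(
        coarse.astype(np.float64), clip.shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    span = raw.max() - raw.min()
    norm = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return SaliencyVolume(map=norm, target_class=target_class, layer=layer, raw=raw)


def render_overlay(
    clip: np.ndarray,
    saliency: SaliencyVolume,
    colormap: str = "jet",
    alpha: float = 0.4,
) -> np.ndarray:
    """Alpha-blend the heatmap over the grayscale frames.

    Blend weight scales with local saliency, so zero-relevance pixels show
    the pure grayscale frame. Returns a (k, H, W, 3) uint8 stack suitable
    for archive or video export.
    """
    clip = np.asarray(clip)
    if clip.shape != saliency.map.shape:
        raise ValidationError(
            f"clip shape {clip.shape} != saliency shape {saliency.map.shape}"
        )
    from matplotlib import colormaps

    cmap = colormaps[colormap]
    heat = cmap(saliency.map)[..., :3]  # (k,H,W,3) floats
    gray = np.repeat((clip.astype(np.float64) / 255.0)[..., None], 3, axis=-1)
    w = alpha * saliency.map[..., None]
    blended = (1.0 - w) * gray + w * heat
    return np.clip(np.rint(blended * 255.0), 0, 255).astype(np.uint8)


def rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation between two maps; 0 by convention when
    either map is constant (correlation undefined)."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValidationError("maps must have identical shapes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    rho = _stats.spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def randomization_sanity(
    classifier: EchoClassifier,
    clip: np.ndarray,
    target_class: int,
    rng: np.random.Generator,
    layer: Optional[str] = None,
) -> float:
    """Model-randomization check: rank correlation between the Grad-CAM map
    and the map after re-initializing the final block and head.

    Low |correlation| indicates the saliency actually depends on the learned
    weights; a value near 1 would mark an input-driven edge detector.
    """
    layer = layer or classifier.last_conv_stage
    original = gradcam3d(classifier, clip, target_class, layer)
    shuffled = copy.deepcopy(classifier)
    names = shuffled.model.stage_names()
    to_reset = names[names.index(layer):]
    for name, mod in shuffled.model.stages:
        if name in to_reset:
            for p in mod.parameters():
                scale = float(p.data.std()) or 1.0
                p.data = rng.normal(0.0, scale, size=p.data.shape).astype(p.data.dtype)
    randomized = gradcam3d(shuffled, clip, target_class, layer)
    return rank_correlation(original.map, randomized.map)
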