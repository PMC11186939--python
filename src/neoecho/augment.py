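"""Training-time augmentation: five intensity and three spatial transforms.

Each transform fires independently with probability ``p_transform`` (0.5) and
the whole sample is augmented at all with probability ``p_sample`` (0.9).
Parameters — and noise realizations — are drawn once per sample and shared by
every frame of a sequence, so augmentation never destroys temporal structure.
Operator order is fixed (intensity before spatial) to make seeded runs
reproducible: sharpness, brightness, gamma, gaussian noise, salt-and-pepper,
speckle, rotation+translation, re-scaling. When both spatial gates fire the
affine parameters are composed and applied in a single resampling pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .types import ValidationError

__all__ = [
    "AugmentConfig",
    "AugmentPlan",
    "gamma_correct",
    "adjust_brightness",
    "adjust_sharpness",
    "add_noise",
    "affine_transform",
    "draw_plan",
    "apply_plan",
    "augment_clip",
    "TRANSFORM_NAMES",
]

TRANSFORM_NAMES = (
    "sharpness",
    "brightness",
    "gamma",
    "gaussian",
    "salt_pepper",
    "speckle",
    "rotate_translate",
    "scale",
)


@dataclass
class AugmentConfig:
    """Ranges and probabilities of the augmentation suite.

    Defaults: blur factor f ∈ [0, 0.9999] or sharpen factor ∈ (1, 8];
    brightness ∈ [0.5, 1.2]; gamma ∈ [0.25, 2.0]; salt-and-pepper per-tail
    probability 0.005; gaussian σ up to 12.75 intensity units (5% of range)
    and speckle strength up to 0.2 (magnitudes are configurable — only the
    transform kinds are fixed); rotation ±15°, translation ≤ 0.1 of the side,
    scaling in [0.8, 1.2].
    """

    p_transform: float = 0.5
    p_sample: float = 0.9
    blur_range: tuple[float, float] = (0.0, 0.9999)
    sharpen_range: tuple[float, float] = (1.0, 8.0)
    brightness_range: tuple[float, float] = (0.5, 1.2)
    gamma_range: tuple[float, float] = (0.25, 2.0)
    salt_pepper_threshold: float = 0.005
    gaussian_sigma_range: tuple[float, float] = (0.0, 12.75)
    speckle_range: tuple[float, float] = (0.0, 0.2)
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    max_translation: float = 0.1
    scale_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        for p in (self.p_transform, self.p_sample):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")


def _as_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """I_γ = 255 · (I/255)^γ, rounded and clipped to 8 bits."""
    if gamma <= 0:
        raise ValidationError(f"gamma must be > 0, got {gamma}")
    return _as_uint8(255.0 * (image.astype(np.float64) / 255.0) ** gamma)


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiply intensities by ``factor`` (<1 darker, >1 brighter)."""
    if factor < 0:
        raise ValidationError(f"brightness factor must be >= 0, got {factor}")
    return _as_uint8(image.astype(np.float64) * factor)


def adjust_sharpness(image: np.ndarray, factor: float) -> np.ndarray:
    """Blend along the blur–original–sharpen axis.

    ``factor`` 0 gives the 3×3 box-smoothed image, 1 the original, and >1
    extrapolates past the original for edge enhancement.
    """
    if factor < 0:
        raise ValidationError(f"sharpness factor must be >= 0, got {factor}")
    img = image.astype(np.float64)
    smooth = ndimage.uniform_filter(img, size=3, mode="nearest")
    return _as_uint8(smooth + factor * (img - smooth))


def add_noise(
    image: np.ndarray,
    kind: str,
    rng: np.random.Generator,
    theta: float = 0.005,
    sigma: float = 0.0,
    strength: float = 0.0,
) -> np.ndarray:
    """Corrupt an 8-bit frame with salt-and-pepper, gaussian or speckle noise.

    Salt-and-pepper uses per-tail probability ``theta`` (a pixel becomes 0
    with probability θ and 255 with probability θ); gaussian adds N(0, σ²) in
    intensity units; speckle multiplies by (1 + ε), ε ~ N(0, strength²).
    """
    if kind == "salt_pepper":
        u = rng.random(image.shape)
        out = image.copy()
        out[u < theta] = 0
        out[u > 1.0 - theta] = 255
        return out
    if kind == "gaussian":
        if sigma == 0:
            return image.copy()
        return _as_uint8(image.astype(np.float64) + rng.normal(0.0, sigma, image.shape))
    if kind == "speckle":
        if strength == 0:
            return image.copy()
        return _as_uint8(
            image.astype(np.float64) * (1.0 + rng.normal(0.0, strength, image.shape))
        )
    raise ValidationError(f"unknown noise kind {kind!r}")


def affine_transform(
    image: np.ndarray,
    angle: float = 0.0,
    tx: float = 0.0,
    ty: float = 0.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Rotate/translate/scale about the image center in one bilinear pass.

    ``tx``/``ty`` are fractions of the side length along columns/rows;
    out-of-frame regions are filled with 0.
    """
    h, w = image.shape[-2:]
    theta = np.deg2rad(angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([ty * h, tx * w])
    # output -> input mapping: invert (scale ∘ rotate about center, then shift)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    m = rot.T / scale
    offset = center - m @ (center + shift)
    out = ndimage.affine_transform(
        image.astype(np.float64), m, offset=offset, order=1, mode="constant", cval=0.0
    )
    return _as_uint8(out)


@dataclass
class AugmentPlan:
    """One sample's frozen augmentation decisions.

    ``active`` maps each transform name to its gate outcome; parameters and
    the noise seed are drawn once so every frame of the sample sees the same
    transform — including identical noise fields.
    """

    augmented: bool
    active: dict
    sharpness: float = 1.0
    brightness: float = 1.0
    gamma: float = 1.0
    gaussian_sigma: float = 0.0
    salt_pepper_theta: float = 0.0
    speckle_strength: float = 0.0
    angle: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    scale: float = 1.0
    noise_seed: int = 0


def draw_plan(config: AugmentConfig, rng: np.random.Generator) -> AugmentPlan:
    """Draw the per-sample gates and shared parameters."""
    augmented = rng.random() < config.p_sample
    gates = rng.random(len(TRANSFORM_NAMES)) < config.p_transform
    active = dict(zip(TRANSFORM_NAMES, (bool(g) for g in gates)))
    # sharpen-vs-blur branch chosen uniformly when the sharpness gate fires
    if rng.random() < 0.5:
        sharp = rng.uniform(*config.blur_range)
    else:
        sharp = rng.uniform(*config.sharpen_range)
    return AugmentPlan(
        augmented=augmented,
        active=active,
        sharpness=float(sharp),
        brightness=float(rng.uniform(*config.brightness_range)),
        gamma=float(rng.uniform(*config.gamma_range)),
        gaussian_sigma=float(rng.uniform(*config.gaussian_sigma_range)),
        salt_pepper_theta=float(config.salt_pepper_threshold),
        speckle_strength=float(rng.uniform(*config.speckle_range)),
        angle=float(rng.uniform(*config.rotation_range)),
        tx=float(rng.uniform(-config.max_translation, config.max_translation)),
        ty=float(rng.uniform(-config.max_translation, config.max_translation)),
        scale=float(rng.uniform(*config.scale_range)),
        noise_seed=int(rng.integers(0, 2**31 - 1)),
    )


def apply_plan(frames: np.ndarray, plan: AugmentPlan) -> np.ndarray:
    """Apply a frozen plan to a frame or (T,H,W) sequence."""
    frames = np.asarray(frames)
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    if not plan.augmented or not any(plan.active.values()):
        out = stack.copy()
        return out[0] if single else out

    shape = stack.shape[1:]
    noise_rng = np.random.default_rng(plan.noise_seed)
    gauss_field = sp_field = speckle_field = None
    if plan.active["gaussian"] and plan.gaussian_sigma > 0:
        gauss_field = noise_rng.normal(0.0, plan.gaussian_sigma, shape)
    if plan.active["salt_pepper"] and plan.salt_pepper_theta > 0:
        sp_field = noise_rng.random(shape)
    if plan.active["speckle"] and plan.speckle_strength > 0:
        speckle_field = noise_rng.normal(0.0, plan.speckle_strength, shape)

    # compose the (at most one) resampling pass for the spatial transforms
    angle = plan.angle if plan.active["rotate_translate"] else 0.0
    tx = plan.tx if plan.active["rotate_translate"] else 0.0
    ty = plan.ty if plan.active["rotate_translate"] else 0.0
    scale = plan.scale if plan.active["scale"] else 1.0
    spatial = plan.active["rotate_translate"] or plan.active["scale"]

    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        img = frame
        if plan.active["sharpness"]:
            img = adjust_sharpness(img, plan.sharpness)
        if plan.active["brightness"]:
            img = adjust_brightness(img, plan.brightness)
        if plan.active["gamma"]:
            img = gamma_correct(img, plan.gamma)
        if gauss_field is not None:
            img = _as_uint8(img.astype(np.float64) + gauss_field)
        if sp_field is not None:
            img = img.copy()
            img[sp_field < plan.salt_pepper_theta] = 0
            img[sp_field > 1.0 - plan.salt_pepper_theta] = 255
        if speckle_field is not None:
            img = _as_uint8(img.astype(np.float64) * (1.0 + speckle_field))
        if spatial:
            img = affine_transform(img, angle=angle, tx=tx, ty=ty, scale=scale)
        out[i] = img
    return out[0] if single else out


def augment_clip(
    frames: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
    return_plan: bool = False,
):
    """Randomly augment a frame or sequence under ``config``.

    With probability 1−p_sample the input is returned unchanged; otherwise
    each transform is gated at p_transform with parameters drawn once and
    shared across frames.
    """
    plan = draw_plan(config, rng)
    out = apply_plan(frames, plan)
    return (out, plan) if return_plan else out
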