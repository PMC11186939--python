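"""Augmentation: operator correctness, gate statistics, frame sharing."""

import numpy as np
import pytest

from neoecho.augment import (
    TRANSFORM_NAMES,
    AugmentConfig,
    adjust_brightness,
    adjust_sharpness,
    affine_transform,
    apply_plan,
    augment_clip,
    draw_plan,
    gamma_correct,
)
from neoecho.types import ValidationError


class TestOperators:
    def test_gamma_worked_example(self):
        # (64/255)^0.5 * 255 = 127.75... -> 128
        img = np.full((8, 8), 64, np.uint8)
        assert (gamma_correct(img, 0.5) == 128).all()
        assert (gamma_correct(img, 1.0) == 64).all()
        # extremes are fixed points of the power law
        ends = np.array([[0, 255]], np.uint8)
        for g in (0.25, 0.5, 2.0):
            assert np.array_equal(gamma_correct(ends, g), ends)
        with pytest.raises(ValidationError):
            gamma_correct(img, 0.0)

    def test_brightness(self):
        img = np.full((4, 4), 100, np.uint8)
        assert (adjust_brightness(img, 0.5) == 50).all()
        assert (adjust_brightness(img, 1.2) == 120).all()
        assert (adjust_brightness(img, 3.0) == 255).all()  # clipped
        with pytest.raises(ValidationError):
            adjust_brightness(img, -1.0)

    def test_sharpness_identity_and_monotone(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (12, 12), np.uint8)
        assert np.array_equal(adjust_sharpness(img, 1.0), img)
        # factor 0 is the box blur: lower variance than the original
        blurred = adjust_sharpness(img, 0.0)
        assert blurred.astype(float).var() < img.astype(float).var()
        # strong sharpening amplifies local contrast on a step edge
        step = np.zeros((9, 9), np.uint8)
        step[:, 4:] = 100
        sharp = adjust_sharpness(step, 4.0).astype(int)
        assert sharp.max() > 100 or sharp[:, :4].min() == 0

    def test_affine_identity(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (16, 16), np.uint8)
        assert np.array_equal(affine_transform(img), img)

    def test_affine_translation_oracle(self):
        img = np.zeros((16, 16), np.uint8)
        img[8, 8] = 200
        out = affine_transform(img, tx=2 / 16.0)  # shift content 2 px right
        assert out[8, 10] == 200
        assert out[8, 8] == 0

    def test_affine_rotation_90(self):
        img = np.zeros((15, 15), np.uint8)
        img[7, 11] = 180  # east of center
        out = affine_transform(img, angle=90.0)
        # 90° rotation about the center moves east to one axis-aligned side
        positions = np.argwhere(out > 90)
        assert len(positions) >= 1
        r, c = positions[0]
        assert abs(int(c) - 7) <= 1 and abs(int(r) - 7) == 4

    def test_affine_scale_grows_blob(self):
        img = np.zeros((32, 32), np.uint8)
        img[12:20, 12:20] = 255
        big = affine_transform(img, scale=1.2)
        small = affine_transform(img, scale=0.8)
        assert (big > 127).sum() > (img > 127).sum() > (small > 127).sum()


class TestPlans:
    def test_gate_statistics(self):
        # 3-sigma check of p_sample and p_transform over many draws
        cfg = AugmentConfig()
        rng = np.random.default_rng(0)
        n = 4000
        plans = [draw_plan(cfg, rng) for _ in range(n)]
        aug_rate = np.mean([p.augmented for p in plans])
        assert abs(aug_rate - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)
        for name in TRANSFORM_NAMES:
            rate = np.mean([p.active[name] for p in plans])
            assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n), name

    def test_parameters_within_ranges(self):
        cfg = AugmentConfig()
        rng = np.random.default_rng(1)
        for _ in range(300):
            p = draw_plan(cfg, rng)
            assert 0.0 <= p.sharpness <= 8.0
            assert 0.5 <= p.brightness <= 1.2
            assert 0.25 <= p.gamma <= 2.0
            assert -15.0 <= p.angle <= 15.0
            assert abs(p.tx) <= 0.1 and abs(p.ty) <= 0.1
            assert 0.8 <= p.scale <= 1.2
            assert p.salt_pepper_theta == 0.005

    def test_plan_shared_across_frames(self):
        # identical frames must stay identical after augmentation — the same
        # parameters AND noise realization apply to every frame
        cfg = AugmentConfig(p_sample=1.0, p_transform=1.0)
        rng = np.random.default_rng(2)
        clip = np.full((5, 24, 24), 120, np.uint8)
        out = augment_clip(clip, cfg, rng)
        for i in range(1, 5):
            assert np.array_equal(out[0], out[i])

    def test_apply_plan_deterministic(self):
        cfg = AugmentConfig(p_sample=1.0, p_transform=1.0)
        rng = np.random.default_rng(3)
        plan = draw_plan(cfg, rng)
        clip = np.random.default_rng(4).integers(0, 256, (3, 16, 16), np.uint8)
        assert np.array_equal(apply_plan(clip, plan), apply_plan(clip, plan))

    def test_unaugmented_passthrough(self):
        cfg = AugmentConfig(p_sample=0.0)
        rng = np.random.default_rng(5)
        clip = np.random.default_rng(6).integers(0, 256, (3, 16, 16), np.uint8)
        out, plan = augment_clip(clip, cfg, rng, return_plan=True)
        assert not plan.augmented
        assert np.array_equal(out, clip)
        assert out is not clip

    def test_single_frame_api(self):
        cfg = AugmentConfig(p_sample=1.0, p_transform=1.0)
        rng = np.random.default_rng(7)
        frame = np.full((16, 16), 60, np.uint8)
        out = augment_clip(frame, cfg, rng)
        assert out.shape == (16, 16)

    def test_salt_pepper_rate(self):
        cfg = AugmentConfig(p_sample=1.0, p_transform=1.0)
        rng = np.random.default_rng(8)
        frame = np.full((200, 200), 128, np.uint8)
        # isolate salt-and-pepper by drawing plans until only it is active
        plan = draw_plan(cfg, rng)
        plan.active = {k: k == "salt_pepper" for k in plan.active}
        out = apply_plan(frame, plan)
        frac0 = (out == 0).mean()
        frac255 = (out == 255).mean()
        sigma = np.sqrt(0.005 * 0.995 / frame.size)
        assert abs(frac0 - 0.005) < 4 * sigma
        assert abs(frac255 - 0.005) < 4 * sigma
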