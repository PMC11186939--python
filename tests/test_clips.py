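"""Frame selection and clip extraction."""

import numpy as np
import pytest

from neoecho.clips import (
    Clip,
    ClipSpec,
    extract_clips,
    relative_ventricle_area,
    select_extreme_frames,
    select_random_frames,
)
from neoecho.types import EchoVideo, MaskSequence, ValidationError, View


def _video(t=30, h=16, w=16):
    rng = np.random.default_rng(t)
    return EchoVideo(frames=rng.integers(0, 256, (t, h, w), np.uint8),
                     fps=25.0, view=View.PSAX_P, subject_id="S", label=0)


class TestClipSpec:
    def test_effective_length(self):
        assert ClipSpec(n=10, k=12, s=1).effective_length == 12
        assert ClipSpec(n=10, k=12, s=2).effective_length == 24
        assert ClipSpec(n=10, k=6, s=2).effective_length == 12

    def test_min_video_length(self):
        assert ClipSpec(k=12, s=1).min_video_length() == 12
        assert ClipSpec(k=12, s=2).min_video_length() == 23

    def test_invalid(self):
        with pytest.raises(ValidationError):
            ClipSpec(n=0)
        with pytest.raises(ValidationError):
            ClipSpec(k=0)
        with pytest.raises(ValidationError):
            ClipSpec(s=0)


class TestVentricleArea:
    def test_known_fraction(self):
        masks = np.zeros((2, 10, 10), np.uint8)
        masks[0, :5] = 1      # half the pixels
        masks[1, :2, :5] = 1  # 10% of the pixels
        areas = relative_ventricle_area(MaskSequence(masks, source="synthetic"))
        assert np.allclose(areas, [0.5, 0.1])

    def test_bad_input(self):
        with pytest.raises(ValidationError):
            relative_ventricle_area(np.zeros((0, 4, 4)))
        with pytest.raises(ValidationError):
            relative_ventricle_area(np.zeros((4, 4)))


class TestExtremeFrames:
    def test_examples(self):
        areas = np.array([0.5, 0.1, 0.9, 0.2, 0.8])
        assert select_extreme_frames(areas, "min", 0.4).tolist() == [1, 3]
        assert select_extreme_frames(areas, "max", 0.2).tolist() == [2]
        assert select_extreme_frames(areas, "min", 1.0).tolist() == [0, 1, 2, 3, 4]

    def test_ceiling_count(self):
        areas = np.arange(10.0)
        assert len(select_extreme_frames(areas, "min", 0.10)) == 1
        assert len(select_extreme_frames(areas, "min", 0.11)) == 2

    def test_ties_take_earlier_frame(self):
        areas = np.array([0.3, 0.3, 0.3, 0.3])
        assert select_extreme_frames(areas, "min", 0.5).tolist() == [0, 1]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            areas = rng.random(rng.integers(3, 30))
            frac = rng.uniform(0.05, 1.0)
            got = select_extreme_frames(areas, "min", frac)
            n_take = int(np.ceil(frac * areas.size))
            # oracle: lexicographic sort on (value, index)
            oracle = sorted(sorted(range(areas.size),
                                   key=lambda i: (areas[i], i))[:n_take])
            assert got.tolist() == oracle
            got_max = select_extreme_frames(areas, "max", frac)
            oracle_max = sorted(sorted(range(areas.size),
                                       key=lambda i: (-areas[i], i))[:n_take])
            assert got_max.tolist() == oracle_max

    def test_systole_found_on_phantom(self, small_synth):
        res = small_synth[0]
        areas = relative_ventricle_area(res.masks)
        idx = select_extreme_frames(areas, "min", 0.1)
        # the selected frames sit at (or next to) the systolic phase
        assert all(res.phase[i] in (0.0, 0.1, 0.9) for i in idx)

    def test_invalid_args(self):
        with pytest.raises(ValidationError):
            select_extreme_frames(np.array([1.0]), "median")
        with pytest.raises(ValidationError):
            select_extreme_frames(np.array([1.0]), "min", 0.0)
        with pytest.raises(ValidationError):
            select_extreme_frames(np.array([]), "min")


class TestRandomFrames:
    def test_distinct_and_in_range(self):
        v = _video(t=20)
        rng = np.random.default_rng(0)
        idx = select_random_frames(v, 15, rng)
        assert len(set(idx.tolist())) == 15
        assert idx.min() >= 0 and idx.max() < 20

    def test_too_many(self):
        with pytest.raises(ValidationError):
            select_random_frames(_video(t=5), 6, np.random.default_rng(0))


class TestExtractClips:
    def test_shapes_and_content(self):
        v = _video(t=30)
        spec = ClipSpec(n=4, k=12, s=1)
        clips = extract_clips(v, spec, np.random.default_rng(1))
        assert len(clips) == 4
        for c in clips:
            assert c.frames.shape == (12, 16, 16)
            assert np.array_equal(c.frames, v.frames[c.frame_indices])
            assert c.label == 0 and c.subject_id == "S"

    def test_stride_two(self):
        v = _video(t=30)
        clips = extract_clips(v, ClipSpec(n=50, k=6, s=2), np.random.default_rng(2))
        for c in clips:
            assert np.array_equal(c.frame_indices, c.start + 2 * np.arange(6))
            assert c.frame_indices[-1] < 30

    def test_exhaustive_start_invariant(self):
        # every start in [0, T-(k-1)s-1] is reachable, none outside
        v = _video(t=16)
        spec = ClipSpec(n=4000, k=6, s=2)
        clips = extract_clips(v, spec, np.random.default_rng(3))
        starts = {c.start for c in clips}
        assert starts == set(range(16 - 5 * 2))

    def test_exact_length_video(self):
        v = _video(t=12)
        clips = extract_clips(v, ClipSpec(n=3, k=12, s=1), np.random.default_rng(4))
        assert all(c.start == 0 for c in clips)

    def test_too_short_video(self):
        with pytest.raises(ValidationError):
            extract_clips(_video(t=11), ClipSpec(k=12, s=1), np.random.default_rng(0))

    def test_clip_validates_frame_count(self):
        with pytest.raises(ValidationError):
            Clip(frames=np.zeros((5, 8, 8), np.uint8), start=0,
                 spec=ClipSpec(k=12), subject_id="S", view="PSAX-P")

    def test_clips_are_copies(self):
        v = _video(t=20)
        clips = extract_clips(v, ClipSpec(n=1, k=12, s=1), np.random.default_rng(5))
        clips[0].frames[:] = 0
        assert v.frames.max() > 0
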