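"""Shared fixtures: small rendered recordings and a trained tiny classifier."""

from __future__ import annotations

import numpy as np
import pytest

from neoecho.classifiers import TrainConfig, build_model, train_classifier
from neoecho.clips import ClipSpec, extract_clips
from neoecho.synth import SynthConfig, render_subject
from neoecho.types import EchoVideo, View


@pytest.fixture(scope="session")
def small_synth():
    """One 40-frame 64×64 PSAX-P recording per severity, fixed seed."""
    out = {}
    for severity in (0, 1, 2):
        cfg = SynthConfig(T=40, H=64, W=64, severity=severity, seed=100 + severity)
        out[severity] = render_subject(cfg, View.PSAX_P)
    return out


@pytest.fixture(scope="session")
def tiny_trained(small_synth):
    """A tiny_3d classifier trained briefly on clips from the three phantom
    severities — enough signal for saliency/prediction plumbing tests."""
    rng = np.random.default_rng(7)
    spec = ClipSpec(n=4, k=12, s=1)
    samples = []
    for severity, result in small_synth.items():
        for clip in extract_clips(result.video, spec, rng):
            samples.append((clip.frames, severity))
    clf = build_model("tiny_3d", num_classes=3, mean=0.45, std=0.25, seed=3)
    train_classifier(clf, samples, TrainConfig(epochs=4, seed=3), rng=rng)
    return clf


@pytest.fixture()
def gradient_video():
    """Deterministic non-synthetic video: per-frame intensity ramps."""
    t, h, w = 6, 32, 32
    base = np.linspace(0, 255, w, dtype=np.float64)
    frames = np.stack(
        [np.clip(np.rint(base[None, :].repeat(h, 0) + 5 * i), 0, 255) for i in range(t)]
    ).astype(np.uint8)
    return EchoVideo(frames=frames, fps=25.0, view=View.PSAX_P, subject_id="G0")
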