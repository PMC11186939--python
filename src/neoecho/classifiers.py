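"""Residual-network classifiers and the balanced training loop.

Three backbone variants share one layer library:

* ``spatial_2d`` — an 18-layer 2D residual network over single frames
  (internally a 3D network with singleton time extents);
* ``spatiotemporal_3d`` — the 18-layer 3D residual network with
  spatio-temporal convolutions over k-frame clips;
* ``tiny_3d`` — a reduced-width 4-block 3D residual network sized for CPU
  training on the synthetic phantom.

Class imbalance is handled by a weighted random sampler: each sample's
weight is the inverse of its class count, so every epoch sees approximately
equal numbers per class. Training minimizes categorical cross-entropy with
Adam (learning rate and weight decay both 0.001 by default) while the
augmentation suite perturbs each drawn sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .augment import AugmentConfig, augment_clip
from .preprocess import normalize_for_model
from .types import ValidationError

__all__ = [
    "TrainConfig",
    "EchoClassifier",
    "build_model",
    "compute_sample_weights",
    "train_classifier",
    "predict",
    "save_classifier",
    "load_classifier",
]


@dataclass
class TrainConfig:
    """Optimization settings. Batch size defaults to 8 for clip models and
    64 for frame models when left as None; ~150 epochs matches the
    full-scale setup, desk-scale runs use 10–30."""

    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 150
    batch_size: Optional[int] = None
    num_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.epochs < 1:
            raise ValidationError("learning rate/weight decay/epochs must be positive")
        if self.num_classes not in (2, 3):
            raise ValidationError(f"num_classes must be 2 or 3, got {self.num_classes}")


class EchoClassifier:
    """A backbone plus the input-normalization contract it was trained with."""

    def __init__(self, model: nn.Model, variant: str, num_classes: int,
                 channels: int = 1, mean: float = 0.0, std: float = 1.0,
                 last_conv_stage: str = ""):
        self.model = model
        self.variant = variant
        self.num_classes = num_classes
        self.channels = channels
        self.mean = mean
        self.std = std
        self.last_conv_stage = last_conv_stage

    @property
    def is_spatial(self) -> bool:
        return self.variant == "spatial_2d"

    def prepare_batch(self, samples: Sequence[np.ndarray]) -> np.ndarray:
        """8-bit frames/clips → float32 (N, C, T, H, W) model input."""
        batch = []
        for s in samples:
            s = np.asarray(s)
            if self.is_spatial:
                if s.ndim != 2:
                    raise ValidationError(
                        f"spatial_2d expects (H, W) frames, got shape {s.shape}"
                    )
                s = s[None]  # singleton time axis
            elif s.ndim != 3:
                raise ValidationError(
                    f"{self.variant} expects (k, H, W) clips, got shape {s.shape}"
                )
            batch.append(normalize_for_model(s, self.mean, self.std, self.channels))
        return np.stack(batch).astype(np.float32)

    def logits(self, samples: Sequence[np.ndarray], train: bool = False) -> np.ndarray:
        self.model.set_training(train)
        return self.model(self.prepare_batch(samples))

    def predict_proba(self, samples: Sequence[np.ndarray], batch_size: int = 16) -> np.ndarray:
        out = []
        for i in range(0, len(samples), batch_size):
            out.append(nn.softmax(self.logits(samples[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)


def _tiny_3d(num_classes: int, channels: int, rng: np.random.Generator) -> tuple[nn.Model, str]:
    stem = nn.Sequential(
        nn.Conv3d(channels, 8, (3, 5, 5), stride=(1, 2, 2), padding=(1, 2, 2), rng=rng),
        nn.BatchNorm(8), nn.ReLU(),
    )
    stages = [
        ("stem", stem),
        ("block1", nn.ResidualBlock3d(8, 16, stride=(2, 2, 2), rng=rng)),
        ("block2", nn.ResidualBlock3d(16, 24, stride=(2, 2, 2), rng=rng)),
        ("block3", nn.ResidualBlock3d(24, 32, stride=(1, 2, 2), rng=rng)),
        ("block4", nn.ResidualBlock3d(32, 32, stride=1, rng=rng)),
        ("gap", nn.GlobalAvgPool()),
        ("fc", nn.Linear(32, num_classes, rng=rng)),
    ]
    return nn.Model(stages), "block4"


def _resnet18(num_classes: int, channels: int, rng: np.random.Generator,
              temporal: bool) -> tuple[nn.Model, str]:
    """18-layer residual network; ``temporal=False`` collapses every kernel
    and stride to a singleton time extent, giving the 2D variant."""
    def k3(kt): return (kt, 3, 3) if temporal else (1, 3, 3)
    t = (lambda v: v) if temporal else (lambda v: 1)
    stem = nn.Sequential(
        nn.Conv3d(channels, 64, (t(3), 7, 7), stride=(1, 2, 2),
                  padding=(t(3) // 2, 3, 3), rng=rng),
        nn.BatchNorm(64), nn.ReLU(),
    )
    def stage(cin, cout, stride):
        return nn.Sequential(
            nn.ResidualBlock3d(cin, cout, stride=(t(stride), stride, stride), rng=rng),
            nn.ResidualBlock3d(cout, cout, stride=1, rng=rng),
        )
    stages = [
        ("stem", stem),
        ("layer1", stage(64, 64, 1)),
        ("layer2", stage(64, 128, 2)),
        ("layer3", stage(128, 256, 2)),
        ("layer4", stage(256, 512, 2)),
        ("gap", nn.GlobalAvgPool()),
        ("fc", nn.Linear(512, num_classes, rng=rng)),
    ]
    return nn.Model(stages), "layer4"


def build_model(
    variant: str,
    num_classes: int = 3,
    pretrained: bool | str = False,
    channels: int = 1,
    mean: float = 0.0,
    std: float = 1.0,
    seed: int = 0,
) -> EchoClassifier:
    """Construct a classifier backbone.

    ``pretrained`` may be a path to a saved parameter archive; passing True
    without a source raises, since no weights ship with the package.
    """
    rng = np.random.default_rng(seed)
    if variant == "tiny_3d":
        model, last = _tiny_3d(num_classes, channels, rng)
    elif variant == "spatiotemporal_3d":
        model, last = _resnet18(num_classes, channels, rng, temporal=True)
    elif variant == "spatial_2d":
        model, last = _resnet18(num_classes, channels, rng, temporal=False)
    else:
        raise ValidationError(
            f"unknown variant {variant!r}; expected tiny_3d, spatiotemporal_3d "
            "or spatial_2d"
        )
    clf = EchoClassifier(model, variant, num_classes, channels, mean, std, last)
    if pretrained:
        if isinstance(pretrained, (str, Path)):
            _load_parameters(clf, pretrained)
        else:
            raise ValidationError(
                "no weights ship with the package; pass pretrained=<path> to "
                "load a saved parameter archive"
            )
    return clf


def compute_sample_weights(labels: Sequence[int]) -> np.ndarray:
    """Inverse-class-count weight per sample: w_i = 1 / count(class(i))."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("no labels given")
    values, counts = np.unique(labels, return_counts=True)
    lut = dict(zip(values.tolist(), counts.tolist()))
    return np.array([1.0 / lut[int(l)] for l in labels])


def train_classifier(
    classifier: EchoClassifier,
    samples: Sequence[tuple[np.ndarray, int]],
    config: TrainConfig,
    augment: Optional[AugmentConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Train in place; returns the history dict.

    Each epoch draws ``len(samples)`` indices with replacement from the
    inverse-class-frequency distribution, augments every drawn sample, and
    minimizes categorical cross-entropy with Adam. History records per-epoch
    mean loss and (post-augmentation) training accuracy. Fixed rng + model
    seed reproduce the loss curve exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = np.array([lab for _, lab in samples], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training requires samples from at least 2 classes")
    if labels.max() >= classifier.num_classes:
        raise ValidationError("label outside the model's class range")
    weights = compute_sample_weights(labels)
    probs = weights / weights.sum()
    batch_size = config.batch_size or (64 if classifier.is_spatial else 8)
    opt = nn.Adam(classifier.model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    n = len(samples)
    history: dict = {"loss": [], "accuracy": []}
    for _epoch in range(config.epochs):
        order = rng.choice(n, size=n, replace=True, p=probs)
        losses, correct = [], 0
        classifier.model.set_training(True)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xs, ys = [], []
            for j in idx:
                frames, lab = samples[j]
                if augment is not None:
                    frames = augment_clip(frames, augment, rng)
                xs.append(frames)
                ys.append(lab)
            x = classifier.prepare_batch(xs)
            y = np.asarray(ys, dtype=int)
            logits = classifier.model(x)
            loss, gl = nn.softmax_cross_entropy(logits, y)
            opt.zero_grad()
            classifier.model.backward(gl)
            opt.step()
            losses.append(loss)
            correct += int((_argmax_high_severity(nn.softmax(logits)) == y).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history


def _argmax_high_severity(probs: np.ndarray) -> np.ndarray:
    """Row argmax with exact ties resolved toward the higher class."""
    k = probs.shape[1]
    return k - 1 - np.argmax(probs[:, ::-1], axis=1)


def predict(
    classifier: EchoClassifier, samples: Sequence[np.ndarray], batch_size: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties → higher severity)."""
    probs = classifier.predict_proba(samples, batch_size=batch_size)
    return probs, _argmax_high_severity(probs)


def save_classifier(classifier: EchoClassifier, path: str | Path) -> Path:
    """Persist parameters + architecture metadata to an .npz archive."""
    path = Path(path)
    params = classifier.model.parameters()
    arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
    # batch-norm running statistics travel with the weights
    running = _collect_running_stats(classifier.model)
    for i, (rm, rv) in enumerate(running):
        arrays[f"rmean_{i}"] = rm
        arrays[f"rvar_{i}"] = rv
    arrays["meta"] = np.array(
        [classifier.variant, str(classifier.num_classes), str(classifier.channels),
         repr(classifier.mean), repr(classifier.std)]
    )
    np.savez_compressed(path, **arrays)
    return path


def load_classifier(path: str | Path) -> EchoClassifier:
    with np.load(path, allow_pickle=False) as data:
        variant, ncls, ch, mean, std = data["meta"]
        clf = build_model(str(variant), int(ncls), channels=int(ch),
                          mean=float(mean), std=float(std))
        _load_into(clf, data)
    return clf


def _load_parameters(classifier: EchoClassifier, path: str | Path) -> None:
    with np.load(path, allow_pickle=False) as data:
        _load_into(classifier, data)


def _load_into(classifier: EchoClassifier, data) -> None:
    params = classifier.model.parameters()
    for i, p in enumerate(params):
        arr = data[f"param_{i}"]
        if arr.shape != p.data.shape:
            raise ValidationError(
                f"parameter {i} shape mismatch: archive {arr.shape} vs model {p.data.shape}"
            )
        p.data = arr.astype(p.data.dtype)
        p.grad = np.zeros_like(p.data)
    bns = _collect_batchnorms(classifier.model)
    for i, bn in enumerate(bns):
        if f"rmean_{i}" in data:
            bn.running_mean = data[f"rmean_{i}"].astype(np.float64)
            bn.running_var = data[f"rvar_{i}"].astype(np.float64)


def _collect_batchnorms(module) -> list:
    out = []
    stack = [module]
    while stack:
        m = stack.pop(0)
        if isinstance(m, nn.BatchNorm):
            out.append(m)
        if isinstance(m, nn.Model):
            stack = [mod for _, mod in m.stages] + stack
        elif isinstance(m, nn.Module):
            children = []
            for v in m.__dict__.values():
                if isinstance(v, nn.Module):
                    children.append(v)
                elif isinstance(v, (list, tuple)):
                    children.extend(x for x in v if isinstance(x, nn.Module))
            stack = children + stack
    return out


def _collect_running_stats(module) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(bn.running_mean, bn.running_var) for bn in _collect_batchnorms(module)]
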