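"""Heatmap-regression landmark detector.

The detector is a compact fully-convolutional encoder implemented directly
on NumPy: two stride-2 max-pool stages bring the input to 1/4 resolution,
where a small convolutional head emits one likelihood map per landmark. Two
normalized coordinate channels are appended to the grayscale input so the
translation-invariant convolutions can disambiguate the subject's right and
left eye, whose local appearance is identical. Training follows the standard
heatmap-regression recipe: Gaussian target maps, mean-squared-error loss,
Adam with a stepped learning-rate schedule, and per-sample augmentation by
in-plane rotation, isotropic scaling and horizontal flips (with the
left/right landmark-role permutation applied alongside the mirror).

Evaluation uses the normalized mean error (NME): per image, the mean
Euclidean landmark error divided by the ground-truth inter-pupillary pixel
distance; the failure rate is the fraction of images with NME above a
threshold (0.1 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .errors import ConfigurationError, EvaluationError, ValidationError
from .heatmaps import HeatmapStack, decode_heatmaps, encode_heatmaps
from .landmarks import LandmarkSet

log = logging.getLogger(__name__)

F32 = np.float32


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol for the landmark detector.

    Defaults mirror a full-scale photographic training run: 512x256 inputs,
    Adam at 1e-3 decayed to 1e-4 at epoch 30 and 1e-5 at epoch 50, batch 16,
    60 epochs, rotation within +/-30 degrees, scaling in [0.75, 1.25],
    horizontal flips with probability 0.5, and a 70/30 train/eval split.
    Desk-scale runs shrink ``input_size`` and ``epochs``.
    """

    input_size: tuple[int, int] = (512, 256)  # (width, height)
    batch_size: int = 16
    epochs: int = 60
    base_lr: float = 1e-3
    lr_milestones: tuple[tuple[int, float], ...] = ((30, 1e-4), (50, 1e-5))
    aug_rotation_deg: float = 30.0
    aug_scale: tuple[float, float] = (0.75, 1.25)
    aug_flip_prob: float = 0.5
    augment: bool = True
    split_fraction: float = 0.70
    seed: int = 0
    backbone: str = "compact"
    stride: int = 4
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValidationError(
                f"split_fraction must be in (0, 1); got {self.split_fraction}"
            )
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        lrs = [self.base_lr] + [lr for _, lr in self.lr_milestones]
        if any(lr <= 0 for lr in lrs):
            raise ValidationError("learning rates must be positive")
        if any(later > earlier for earlier, later in zip(lrs, lrs[1:])):
            raise ValidationError("learning rates must be non-increasing")
        w, h = self.input_size
        if w % self.stride or h % self.stride:
            raise ValidationError(
                f"input_size {self.input_size} must be a multiple of stride {self.stride}"
            )

    def lr_at(self, epoch: int) -> float:
        lr = self.base_lr
        for milestone, value in self.lr_milestones:
            if epoch >= milestone:
                lr = value
        return lr


# ---------------------------------------------------------------------------
# minimal NumPy conv-net layers
# ---------------------------------------------------------------------------

class _Conv:
    """Same-padded 2D convolution via im2col; float32 throughout.

    ``dilation`` spaces the kernel taps to widen the receptive field without
    extra parameters.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, k, dilation
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, hh, ww = x.shape
        k, d = self.k, self.d
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ext = d * (k - 1) + 1  # dilated kernel extent
        win = np.lib.stride_tricks.sliding_window_view(xp, (ext, ext), axis=(2, 3))
        win = win[:, :, :, :, ::d, ::d]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, hh * ww, c * k * k)
        cols = np.ascontiguousarray(cols)
        out = cols @ self.w.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, hh, ww)

    def backward(self, dout: np.ndarray):
        cols, xshape = self._cache
        n, c, hh, ww = xshape
        k, d = self.k, self.d
        p = d * (k // 2)
        dmat = dout.reshape(n, self.c_out, hh * ww).transpose(0, 2, 1)
        self.dw = np.einsum("npo,npc->oc", dmat, cols, optimize=True)
        self.db = dmat.sum(axis=(0, 1))
        dcols = (dmat @ self.w).reshape(n, hh, ww, c, k, k)
        dxp = np.zeros((n, c, hh + 2 * p, ww + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d : i * d + hh, j * d : j * d + ww] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + hh, p : p + ww] if p else dxp

    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray):
        return dout * self._mask

    def grads(self):
        return []


class _MaxPool2:
    """2x2 max pooling with stride 2 (input sides must be even)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, hh, ww = x.shape
        r = x.reshape(n, c, hh // 2, 2, ww // 2, 2)
        out = r.max(axis=(3, 5))
        if train:
            self._mask = r == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray):
        n, c, hh, ww = self._shape
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(n, c, hh, ww).astype(F32)

    def grads(self):
        return []


def _build_compact(rng: np.random.Generator) -> list:
    """Small encoder: 3 input channels -> 10 heatmaps at 1/4 resolution.

    The two dilated stages widen the receptive field to roughly 90 input
    pixels so corner landmarks (the canthi) see the whole eye for context.
    """
    return [
        _Conv(3, 16, 3, rng),
        _ReLU(),
        _MaxPool2(),
        _Conv(16, 24, 3, rng),
        _ReLU(),
        _MaxPool2(),
        _Conv(24, 32, 3, rng),
        _ReLU(),
        _Conv(32, 32, 3, rng, dilation=2),
        _ReLU(),
        _Conv(32, 32, 3, rng, dilation=4),
        _ReLU(),
        _Conv(32, 10, 1, rng),
    ]


#: Registry of backbone builders; each maps an init RNG to a layer list that
#: turns (N, 3, h, w) inputs into (N, 10, h/4, w/4) heatmaps.
BACKBONES: dict[str, Callable[[np.random.Generator], list]] = {
    "compact": _build_compact,
}


def register_backbone(name: str, builder: Callable[[np.random.Generator], list]) -> None:
    BACKBONES[name] = builder


class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# model handle
# ---------------------------------------------------------------------------

@dataclass
class LandmarkModel:
    """A trained detector: backbone layers plus the input/output geometry."""

    layers: list
    config: TrainConfig

    @property
    def input_size(self) -> tuple[int, int]:
        return self.config.input_size

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        out = batch
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        meta = json.dumps(
            {
                "backbone": self.config.backbone,
                "input_size": list(self.config.input_size),
                "stride": self.config.stride,
                "sigma": self.config.sigma,
                "seed": self.config.seed,
            }
        )
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        config = TrainConfig(
            input_size=tuple(meta["input_size"]),
            stride=meta["stride"],
            sigma=meta["sigma"],
            seed=meta["seed"],
            backbone=meta["backbone"],
        )
        model = cls(
            layers=BACKBONES[meta["backbone"]](np.random.default_rng(0)),
            config=config,
        )
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(F32) / 255.0
    else:
        img = img.astype(F32)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114], dtype=F32)
    return img.astype(F32)


def _resize_to_input(
    image: np.ndarray, input_size: tuple[int, int]
) -> tuple[np.ndarray, tuple[float, float]]:
    """Anisotropic stretch; returns the gray raster and (sx, sy) scale factors."""
    w, h = input_size
    gray = _to_gray(image)
    oh, ow = gray.shape
    sx, sy = w / ow, h / oh
    if (ow, oh) != (w, h):
        gray = resize(gray, (h, w), order=1, anti_aliasing=sx < 1 or sy < 1).astype(F32)
    return gray, (sx, sy)


def _map_points_to_input(pts: np.ndarray, sx: float, sy: float) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = (out[:, 0] + 0.5) * sx - 0.5
    out[:, 1] = (out[:, 1] + 0.5) * sy - 0.5
    return out


def _map_points_from_input(pts: np.ndarray, sx: float, sy: float) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = (out[:, 0] + 0.5) / sx - 0.5
    out[:, 1] = (out[:, 1] + 0.5) / sy - 0.5
    return out


def _net_input(gray: np.ndarray) -> np.ndarray:
    """Stack grayscale with normalized x/y coordinate channels."""
    h, w = gray.shape
    xx = np.linspace(-1.0, 1.0, w, dtype=F32)[None, :].repeat(h, axis=0)
    yy = np.linspace(-1.0, 1.0, h, dtype=F32)[:, None].repeat(w, axis=1)
    return np.stack([gray - 0.5, xx, yy]).astype(F32)


def augment_sample(
    image: np.ndarray,
    landmarks: LandmarkSet,
    rng: np.random.Generator,
    config: TrainConfig,
) -> tuple[np.ndarray, LandmarkSet]:
    """One random affine + flip draw applied identically to raster and points.

    Rotation is about the image centre, scaling is isotropic, and horizontal
    flips mirror the raster while permuting the landmark roles so the
    subject's right-eye block stays anatomically right. If the transformed
    landmarks leave the frame after five re-draws the sample is returned
    unaugmented.
    """
    h, w = image.shape[:2]
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    for _ in range(5):
        angle = rng.uniform(-config.aug_rotation_deg, config.aug_rotation_deg)
        scale = rng.uniform(*config.aug_scale)
        flip = rng.random() < config.aug_flip_prob
        if angle == 0.0 and scale == 1.0 and not flip:
            return image, landmarks
        tform = (
            AffineTransform(translation=-c)
            + AffineTransform(rotation=np.deg2rad(angle), scale=scale)
            + AffineTransform(translation=c)
        )
        pts = landmarks.transformed(tform.params)
        if flip:
            pts = pts.flipped(w)
        p = pts.points
        if (
            p[:, 0].min() >= 0
            and p[:, 1].min() >= 0
            and p[:, 0].max() <= w - 1
            and p[:, 1].max() <= h - 1
        ):
            out = warp(
                image, tform.inverse, order=1, mode="edge", preserve_range=True
            ).astype(image.dtype)
            if flip:
                out = out[:, ::-1].copy()
            return out, pts
    log.warning("augmentation left the frame 5 times; sample kept unaugmented")
    return image, landmarks


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _coerce_pairs(dataset: Sequence) -> list[tuple[np.ndarray, LandmarkSet]]:
    pairs = []
    for item in dataset:
        if hasattr(item, "landmarks_true"):
            pairs.append((item.image, item.landmarks_true))
        else:
            image, landmarks = item
            pairs.append((np.asarray(image), landmarks))
    return pairs


@dataclass
class TrainResult:
    model: LandmarkModel
    epoch_losses: list[float]
    train_indices: np.ndarray
    eval_indices: np.ndarray


def fit(
    dataset: Sequence,
    config: TrainConfig,
    indices: Sequence[int] | None = None,
) -> tuple[LandmarkModel, list[float]]:
    """Train a detector on the given samples (no splitting); returns the
    model handle and the mean heatmap loss per epoch."""
    pairs = _coerce_pairs(dataset)
    if indices is not None:
        pairs = [pairs[i] for i in indices]
    if not pairs:
        raise ConfigurationError("cannot train on an empty sample list")

    w, h = config.input_size
    prepped = []
    for image, landmarks in pairs:
        gray, (sx, sy) = _resize_to_input(image, config.input_size)
        prepped.append((gray, LandmarkSet(_map_points_to_input(landmarks.points, sx, sy))))

    ss = np.random.SeedSequence(config.seed)
    init_seed, aug_seed, shuffle_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))
    model = LandmarkModel(
        layers=BACKBONES[config.backbone](np.random.default_rng(init_seed)),
        config=config,
    )
    optim = _Adam(model.parameters())
    aug_rng = np.random.default_rng(aug_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)

    n = len(prepped)
    losses: list[float] = []
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            inputs, targets = [], []
            for bi in batch_idx:
                gray, marks = prepped[bi]
                if config.augment:
                    gray, marks = augment_sample(gray, marks, aug_rng, config)
                inputs.append(_net_input(gray))
                targets.append(
                    encode_heatmaps(
                        marks, (w, h), stride=config.stride, sigma=config.sigma
                    ).maps.astype(F32)
                )
            x = np.stack(inputs)
            t = np.stack(targets)
            out = model.forward(x, train=True)
            diff = out - t
            loss = float(np.mean(diff * diff))
            model.backward((2.0 / diff.size) * diff.astype(F32))
            optim.step(model.gradients(), lr)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        log.info("epoch %d/%d lr=%.1e loss=%.3e", epoch + 1, config.epochs, lr, losses[-1])
    return model, losses


def split_dataset(n: int, config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic face-level train/eval partition."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5EED)).generate_state(1)[0])
    perm = rng.permutation(n)
    n_train = int(round(config.split_fraction * n))
    train_idx, eval_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if len(train_idx) == 0 or len(eval_idx) == 0:
        raise ConfigurationError(
            f"split of {n} samples at fraction {config.split_fraction} "
            "leaves an empty partition"
        )
    return train_idx, eval_idx


def train(dataset: Sequence, config: TrainConfig) -> TrainResult:
    """Split the dataset, train on the training partition, return the handle.

    The split is deterministic in ``config.seed`` and happens at the face
    level (one image per face here).
    """
    pairs = _coerce_pairs(dataset)
    if not pairs:
        raise ConfigurationError("dataset is empty")
    train_idx, eval_idx = split_dataset(len(pairs), config)
    model, losses = fit(pairs, config, indices=train_idx)
    return TrainResult(
        model=model,
        epoch_losses=losses,
        train_indices=train_idx,
        eval_indices=eval_idx,
    )


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict(model: LandmarkModel, image: np.ndarray) -> LandmarkSet:
    """Detect the ten landmarks in one image, in original-image coordinates."""
    gray, (sx, sy) = _resize_to_input(image, model.input_size)
    out = model.forward(_net_input(gray)[None], train=False)[0]
    stack = HeatmapStack(out.astype(float), stride=model.config.stride, sigma=model.config.sigma)
    marks = decode_heatmaps(stack, stride=model.config.stride)
    return LandmarkSet(_map_points_from_input(marks.points, sx, sy))


@dataclass
class EvalResult:
    """Localization quality over an image set."""

    per_image_nme: np.ndarray
    mean_nme: float
    failure_rate: float
    threshold: float = 0.1


def nme(prediction: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean Euclidean landmark error over the ground-truth inter-pupil distance."""
    norm = truth.interpupillary_px()
    if norm <= 0:
        raise EvaluationError("ground-truth inter-pupillary distance is zero")
    err = np.linalg.norm(prediction.points - truth.points, axis=1)
    return float(err.mean() / norm)


def evaluate(
    predictions: Sequence[LandmarkSet],
    truths: Sequence[LandmarkSet],
    threshold: float = 0.1,
) -> EvalResult:
    """Compute per-image NME, its mean, and the failure rate at ``threshold``."""
    if len(predictions) != len(truths):
        raise ValidationError(
            f"got {len(predictions)} predictions for {len(truths)} truths"
        )
    if not predictions:
        raise ValidationError("nothing to evaluate")
    values = np.array([nme(p, t) for p, t in zip(predictions, truths)])
    return EvalResult(
        per_image_nme=values,
        mean_nme=float(values.mean()),
        failure_rate=float(np.mean(values > threshold)),
        threshold=threshold,
    )


def evaluate_model(
    model: LandmarkModel, samples: Sequence, threshold: float = 0.1
) -> EvalResult:
    """Predict on each sample and evaluate against its ground truth."""
    pairs = _coerce_pairs(samples)
    preds = [predict(model, image) for image, _ in pairs]
    truths = [marks for _, marks in pairs]
    return evaluate(preds, truths, threshold=threshold)
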