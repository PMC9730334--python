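"""Segmentation-network wiring contract, evaluation metrics and training
arithmetic.

The segmentation backbone is MobileNetV2 feeding a DeepLabV3+ head: an
inverted-residual encoder truncated at its 320-channel stage, ASPP over
the deep feature, and a decoder that concatenates the 4x-upsampled ASPP
output with a projected stride-4 shallow skip (24 channels), refines with
two 3x3 stages and upsamples by 4 twice back to full resolution.  This
module captures that wiring as an explicit shape calculus — every stage's
feature-map side and channel count — which is what integration code and
tests need; the tensor arithmetic itself belongs to a deep-learning
framework and is out of scope here.

Also here: ReLU6, the depthwise-separable convolution cost model
(cost ratio 1/N + 1/DK^2 versus standard convolution), the per-class
confusion matrix with MIoU/mPA, a bias-corrected Adam step, a
PASCAL-VOC-layout dataset reader, and a small numpy per-pixel segmenter
used to smoke-test the two-phase (frozen/unfrozen) training schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConvCost",
    "ModelConfig",
    "TrainConfig",
    "AdamState",
    "StageShape",
    "ModelDescription",
    "ConfusionMatrix",
    "relu6",
    "conv_costs",
    "build_model",
    "confusion_accumulate",
    "miou",
    "mpa",
    "adam_step",
    "cosine_lr",
    "read_voc_split",
    "PixelSegmenter",
]


def relu6(x):
    """min(max(0, x), 6) elementwise — bounded activation for low-precision
    inference."""
    return np.minimum(np.maximum(0, np.asarray(x)), 6)


@dataclass(frozen=True)
class ConvCost:
    DK: int
    DF: int
    M: int
    N: int
    std_cost: int
    dsc_cost: int
    ratio: float


def conv_costs(DK: int, DF: int, M: int, N: int) -> ConvCost:
    """Multiply-accumulate counts of a standard vs depthwise-separable conv.

    std = DK^2 M DF^2 N; dsc = DK^2 M DF^2 + M N DF^2 (depthwise spatial
    pass plus 1x1 pointwise mixing); the ratio dsc/std simplifies to
    1/N + 1/DK^2 — about one ninth for a 3x3 kernel and many filters.
    """
    for v in (DK, DF, M, N):
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError(f"all of DK, DF, M, N must be positive integers, got {v!r}")
    std = DK * DK * M * DF * DF * N
    dsc = DK * DK * M * DF * DF + M * N * DF * DF
    return ConvCost(DK, DF, M, N, std, dsc, dsc / std)


# ---------------------------------------------------------------------------
# wiring contract


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 2
    input_side: int = 512
    downsample_factor: int = 16
    aspp_channels: int = 256
    decoder_skip_channels: int = 48

    def __post_init__(self) -> None:
        if self.downsample_factor not in (8, 16):
            raise ValueError(f"downsample_factor must be 8 or 16, got {self.downsample_factor}")
        if self.input_side % self.downsample_factor:
            raise ValueError("input_side must be divisible by downsample_factor")


@dataclass(frozen=True)
class StageShape:
    name: str
    side: int
    channels: int
    stride: int  # cumulative input/feature ratio
    dilation: int = 1


# MobileNetV2 inverted-residual settings: (expansion, channels, repeats, stride)
_MBV2_BLOCKS = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


@dataclass(frozen=True)
class ModelDescription:
    config: ModelConfig
    stages: list[StageShape]
    deepest_feature: StageShape
    shallow_skip: StageShape
    aspp_rates: tuple[int, int, int]

    def forward_shape(self, side: int | None = None):
        """Shape-level forward pass: input side -> output (side, channels)."""
        cfg = self.config
        s = cfg.input_side if side is None else side
        if s % cfg.downsample_factor:
            raise ValueError("input side must be divisible by downsample_factor")
        return (s, s, cfg.num_classes)


def build_model(cfg: ModelConfig | None = None) -> ModelDescription:
    """Lay out the encoder/decoder stages and their feature-map shapes.

    The encoder is the 17-block inverted-residual backbone truncated at
    the 320-channel stage.  When the cumulative stride would exceed the
    configured downsample factor, further stride-2 blocks run stride 1
    with doubled dilation (atrous), so the deepest map keeps side
    input_side / downsample_factor.  A 512x512 input yields a 32x32x320
    deepest feature (factor 16) and a 128x128x24 shallow skip.
    """
    cfg = cfg or ModelConfig()
    side = cfg.input_side
    stages: list[StageShape] = []
    stride, dilation = 2, 1
    side //= 2
    stages.append(StageShape("stem_conv3x3", side, 32, stride))
    shallow = None
    for t, c, n, s in _MBV2_BLOCKS:
        for i in range(n):
            s_i = s if i == 0 else 1
            if s_i == 2 and stride * 2 > cfg.downsample_factor:
                dilation *= 2
                s_i = 1
            if s_i == 2:
                stride *= 2
                side //= 2
            stages.append(
                StageShape(f"inverted_residual_t{t}_c{c}", side, c, stride, dilation)
            )
        if c == 24:
            shallow = stages[-1]
    deepest = stages[-1]
    rates = (6, 12, 18) if cfg.downsample_factor == 16 else (12, 24, 36)
    stages.append(StageShape("aspp", deepest.side, cfg.aspp_channels, stride, dilation))
    up_side = deepest.side * 4
    stages.append(
        StageShape(
            "decoder_concat",
            up_side,
            cfg.aspp_channels + cfg.decoder_skip_channels,
            cfg.downsample_factor // 4,
        )
    )
    stages.append(StageShape("decoder_refine3x3_a", up_side, cfg.aspp_channels, cfg.downsample_factor // 4))
    stages.append(StageShape("decoder_refine3x3_b", up_side, cfg.aspp_channels, cfg.downsample_factor // 4))
    stages.append(StageShape("classifier_upsample4x_twice", cfg.input_side, cfg.num_classes, 1))
    assert shallow is not None and shallow.channels == 24
    return ModelDescription(cfg, stages, deepest, shallow, rates)


# ---------------------------------------------------------------------------
# metrics


class ConfusionMatrix:
    """Per-class confusion counts p[i, j] (truth i, prediction j),
    accumulable across images."""

    def __init__(self, num_classes: int):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.num_classes = num_classes
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def add(self, truth: np.ndarray, pred: np.ndarray) -> "ConfusionMatrix":
        t = np.asarray(truth).ravel()
        p = np.asarray(pred).ravel()
        if t.shape != p.shape:
            raise ValueError("truth and prediction shapes differ")
        if t.min() < 0 or p.min() < 0 or t.max() >= self.num_classes or p.max() >= self.num_classes:
            raise ValueError(f"labels must lie in [0, {self.num_classes})")
        np.add.at(self.counts, (t, p), 1)
        return self

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp


def confusion_accumulate(pred, truth, num_classes: int) -> ConfusionMatrix:
    return ConfusionMatrix(num_classes).add(truth, pred)


def miou(cm: ConfusionMatrix) -> float:
    """Mean intersection-over-union: mean over classes of
    TP / (TP + FP + FN); classes absent from both truth and prediction
    are excluded from the mean."""
    union = cm.tp + cm.fp + cm.fn
    present = union > 0
    if not present.any():
        raise ValueError("confusion matrix is empty")
    return float((cm.tp[present] / union[present]).mean())


def mpa(cm: ConfusionMatrix) -> float:
    """Mean per-class pixel accuracy: mean over classes of
    TP / (TP + FN), skipping classes absent from the ground truth."""
    denom = cm.tp + cm.fn
    present = denom > 0
    if not present.any():
        raise ValueError("confusion matrix is empty")
    return float((cm.tp[present] / denom[present]).mean())


# ---------------------------------------------------------------------------
# optimizer


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    freeze_epochs: int = 50
    batch_frozen: int = 8
    batch_unfrozen: int = 4
    lr0: float = 1e-3
    scheduler: str = "cos"
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 5e-4
    gamma: float = 0.94  # step-decay factor; stored but unused under "cos"
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")
        if self.freeze_epochs > self.epochs:
            raise ValueError("freeze_epochs cannot exceed epochs")
        if self.scheduler not in ("cos", "step"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0
    epsilon: float = 1e-8

    @classmethod
    def zeros_like(cls, params: np.ndarray, epsilon: float = 1e-8) -> "AdamState":
        return cls(m=np.zeros_like(params, dtype=float),
                   v=np.zeros_like(params, dtype=float), t=0, epsilon=epsilon)


def adam_step(state: AdamState, grads: np.ndarray, params: np.ndarray,
              cfg: TrainConfig, lr: float | None = None):
    """One bias-corrected Adam update; returns (state, new_params).

    t += 1; m = b1 m + (1-b1) g; v = b2 v + (1-b2) g^2;
    m_hat = m/(1-b1^t); v_hat = v/(1-b2^t);
    theta -= lr * m_hat / (sqrt(v_hat) + eps).
    """
    g = np.asarray(grads, dtype=float)
    p = np.asarray(params, dtype=float)
    if g.shape != p.shape or g.shape != state.m.shape:
        raise ValueError("grads, params and moments must share a shape")
    lr = cfg.lr0 if lr is None else lr
    t = state.t + 1
    m = cfg.beta1 * state.m + (1 - cfg.beta1) * g
    v = cfg.beta2 * state.v + (1 - cfg.beta2) * g * g
    m_hat = m / (1 - cfg.beta1 ** t)
    v_hat = v / (1 - cfg.beta2 ** t)
    new_p = p - lr * m_hat / (np.sqrt(v_hat) + state.epsilon)
    return AdamState(m=m, v=v, t=t, epsilon=state.epsilon), new_p


def cosine_lr(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at *epoch* under the configured scheduler."""
    if cfg.scheduler == "cos":
        return cfg.lr0 * 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.epochs, 1)))
    return cfg.lr0 * cfg.gamma ** epoch


# ---------------------------------------------------------------------------
# data + training smoke


def read_voc_split(root: str | Path, split: str = "train"):
    """Read a PASCAL-VOC-layout dataset split.

    Expects ``JPEGImages/``, ``SegmentationClass/`` and
    ``ImageSets/Segmentation/{split}.txt`` under *root*; returns a list of
    (image_path, mask_path) pairs.
    """
    root = Path(root)
    listing = root / "ImageSets" / "Segmentation" / f"{split}.txt"
    if not listing.exists():
        raise FileNotFoundError(listing)
    pairs = []
    for name in listing.read_text().split():
        img = root / "JPEGImages" / f"{name}.jpg"
        if not img.exists():
            img = root / "JPEGImages" / f"{name}.png"
        pairs.append((img, root / "SegmentationClass" / f"{name}.png"))
    return pairs


class PixelSegmenter:
    """Tiny per-pixel segmenter for exercising the training schedule.

    A fixed-size feature stage (one 3x3 convolution kernel per input
    channel) feeds a per-pixel logistic classifier.  During the frozen
    phase only the classifier trains; afterwards both parameter groups
    do.  Small by design — its job is to verify that the two-phase
    schedule, the cosine learning-rate curve and the Adam recurrence fit
    together, not to segment real leaves.
    """

    def __init__(self, in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = rng.normal(0, 0.1, size=(in_channels, 3, 3))
        self.w = np.zeros(2 * in_channels + 1)
        self._st_k = AdamState.zeros_like(self.kernels)
        self._st_w = AdamState.zeros_like(self.w)

    def _features(self, img: np.ndarray) -> np.ndarray:
        from scipy.ndimage import convolve

        x = np.asarray(img, dtype=float) / 255.0
        if x.ndim == 2:
            x = x[..., None]
        feats = [x[..., c] for c in range(x.shape[-1])]
        for c in range(x.shape[-1]):
            feats.append(convolve(x[..., c], self.kernels[c], mode="nearest"))
        feats.append(np.ones(x.shape[:2]))
        return np.stack(feats, axis=-1)

    def _forward(self, img: np.ndarray) -> np.ndarray:
        z = self._features(img) @ self.w
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))

    def predict(self, img: np.ndarray) -> np.ndarray:
        return (self._forward(img) > 0.5).astype(np.uint8)

    def loss(self, img: np.ndarray, mask: np.ndarray) -> float:
        p = np.clip(self._forward(img), 1e-7, 1 - 1e-7)
        y = np.asarray(mask, dtype=float)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    def _grads(self, img: np.ndarray, mask: np.ndarray):
        f = self._features(img)
        p = self._forward(img)
        y = np.asarray(mask, dtype=float)
        err = (p - y) / y.size
        gw = np.tensordot(err, f, axes=((0, 1), (0, 1)))
        x = np.asarray(img, dtype=float) / 255.0
        if x.ndim == 2:
            x = x[..., None]
        c_in = x.shape[-1]
        gk = np.zeros_like(self.kernels)
        for c in range(c_in):
            # kernel gradient of the conv feature: correlation of the
            # upstream error with the input channel
            up = err * self.w[c_in + c]
            gk[c] = _kernel_grad(x[..., c], up)
        return gk, gw

    def train(self, images, masks, cfg: TrainConfig, seed: int = 0):
        """Two-phase minibatch training; returns per-epoch mean losses."""
        rng = np.random.default_rng(seed)
        n = len(images)
        history = []
        for epoch in range(cfg.epochs):
            frozen = epoch < cfg.freeze_epochs
            batch = cfg.batch_frozen if frozen else cfg.batch_unfrozen
            lr = cosine_lr(cfg, epoch)
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                gk = np.zeros_like(self.kernels)
                gw = np.zeros_like(self.w)
                for i in idx:
                    gki, gwi = self._grads(images[i], masks[i])
                    gk += gki / len(idx)
                    gw += gwi / len(idx)
                self._st_w, self.w = adam_step(self._st_w, gw, self.w, cfg, lr)
                if not frozen:
                    self._st_k, self.kernels = adam_step(self._st_k, gk, self.kernels, cfg, lr)
            history.append(float(np.mean([self.loss(im, mk) for im, mk in zip(images, masks)])))
        return history

    def save(self, path: str | Path) -> None:
        np.savez(path, kernels=self.kernels, w=self.w)

    @classmethod
    def load(cls, path: str | Path) -> "PixelSegmenter":
        data = np.load(path)
        model = cls(in_channels=data["kernels"].shape[0])
        model.kernels = data["kernels"]
        model.w = data["w"]
        return model


def _kernel_grad(x: np.ndarray, upstream: np.ndarray) -> np.ndarray:
    """Gradient of sum(upstream * conv3x3(x, k)) with respect to k."""
    g = np.empty((3, 3))
    h, w = x.shape
    xp = np.pad(x, 1, mode="edge")
    for di in range(3):
        for dj in range(3):
            # scipy convolve flips the kernel: out[i,j] = sum_k x[i+1-di, j+1-dj] k[di,dj]
            g[di, dj] = (upstream * xp[1 - di + 1 : 1 - di + 1 + h, 1 - dj + 1 : 1 - dj + 1 + w]).sum()
    return g
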