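"""Per-class binary semantic segmentation (Retina-Unet).

One binary U-Net per anatomy/lesion class, built on a residual 18-layer
encoder.  At width multiplier 1 and 256x256 input the forward pass
realizes the reference shape progression:

    256x256x3 -> 128x128x64 -> (pool) 64x64x64 -> encoder out 8x8x512
    -> decoder stages from 16x16x256 down to 256x256x16 -> head 256x256x1

Each encoder stage's feature map is skip-concatenated to the matching
decoder stage.  A width multiplier in (0, 1] scales every channel count
(spatial sizes are untouched) so the same architecture trains at desk
scale on a single CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .exceptions import (
    DegenerateStatsError,
    MaskValidationError,
    ParameterError,
    ShapeMismatchError,
)
from .fusion import FundusImage

# ---------------------------------------------------------------------------
# dataset normalization


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and RMS deviation of a fundus image dataset.

    The spread is the root mean square of mean-subtracted pixel values
    (i.e. the population standard deviation), kept in float64 so at
    least 8 decimal digits survive.
    """

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise DegenerateStatsError(
                f"per-channel std must be strictly positive, got {self.std}"
            )


def compute_normalization_stats(
    images: Iterable[np.ndarray | FundusImage],
) -> NormalizationStats:
    """Two-pass per-channel mean and RMS over all pixels of all images."""
    arrays = [
        (im.pixels if isinstance(im, FundusImage) else np.asarray(im)).astype(
            np.float64
        )
        for im in images
    ]
    if not arrays:
        raise ParameterError("at least one image required")
    n_pix = sum(a.shape[0] * a.shape[1] for a in arrays)
    mean = sum(a.sum(axis=(0, 1)) for a in arrays) / n_pix
    sq = sum(((a - mean) ** 2).sum(axis=(0, 1)) for a in arrays) / n_pix
    std = np.sqrt(sq)
    return NormalizationStats(mean=tuple(mean), std=tuple(std))


def normalize_image(
    img: np.ndarray | FundusImage,
    stats: NormalizationStats,
    size: int = 256,
) -> np.ndarray:
    """Resize (bilinear) to size x size and standardize -> float32 HWC."""
    arr = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if arr.shape[:2] != (size, size):
        arr = _sk_resize(
            arr.astype(np.float32),
            (size, size),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
    out = (arr.astype(np.float64) - np.asarray(stats.mean)) / np.asarray(stats.std)
    return out.astype(np.float32)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize for binary label planes."""
    if mask.shape == (size, size):
        return (mask > 0).astype(np.uint8)
    out = _sk_resize(
        mask.astype(np.float32),
        (size, size),
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    )
    return (out > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# model


@dataclass
class SegmentationModelSpec:
    """Architecture of one binary Retina-Unet."""

    target_class: str = ""
    input_size: int = 256
    width_multiplier: float = 1.0
    base_widths: tuple[int, int, int, int, int] = (64, 128, 256, 512, 32)
    # (stem/stage1, stage2, stage3, stage4, second-to-last decoder width)

    def __post_init__(self) -> None:
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ParameterError(
                f"width multiplier must be in (0, 1], got {self.width_multiplier}"
            )
        if self.input_size % 32 != 0:
            raise ParameterError("input size must be a multiple of 32")

    def width(self, base: int) -> int:
        return max(1, math.ceil(base * self.width_multiplier))


class _ResidualBlock(nn.Layer):
    """Two 3x3 convolutions with identity (or projected) shortcut."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        self.relu2 = nn.ReLU()
        if stride != 1 or cin != cout:
            self.short = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False),
                nn.BatchNorm2d(cout),
            )
        else:
            self.short = None

    def forward(self, x, train=True):
        h = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        m = self.bn2.forward(self.conv2.forward(h, train), train)
        s = self.short.forward(x, train) if self.short is not None else x
        return self.relu2.forward(m + s, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dm = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))
            )
        )
        ds = self.short.backward(d) if self.short is not None else d
        return dm + ds

    def params(self):
        ps = self.conv1.params() + self.bn1.params()
        ps += self.conv2.params() + self.bn2.params()
        if self.short is not None:
            ps += self.short.params()
        return ps

    def state(self):
        s = {
            "conv1": self.conv1.state(),
            "bn1": self.bn1.state(),
            "conv2": self.conv2.state(),
            "bn2": self.bn2.state(),
        }
        if self.short is not None:
            s["short"] = self.short.state()
        return s

    def load_state(self, s):
        self.conv1.load_state(s["conv1"])
        self.bn1.load_state(s["bn1"])
        self.conv2.load_state(s["conv2"])
        self.bn2.load_state(s["bn2"])
        if self.short is not None:
            self.short.load_state(s["short"])


class _DecoderStage(nn.Layer):
    """Upsample 2x, concatenate the encoder skip, 3x3 conv + BN + ReLU."""

    def __init__(self, cin, cskip, cout, rng):
        self.up = nn.UpsampleNearest2x()
        self.cskip = cskip
        self.conv = nn.Conv2d(cin + cskip, cout, 3, rng=rng, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()

    def forward(self, x, skip, train=True):
        u = self.up.forward(x, train)
        self._cin = u.shape[1]
        h = np.concatenate([u, skip], axis=1) if skip is not None else u
        return self.relu.forward(self.bn.forward(self.conv.forward(h, train), train), train)

    def backward(self, dout):
        d = self.conv.backward(self.bn.backward(self.relu.backward(dout)))
        du, dskip = d[:, : self._cin], d[:, self._cin :]
        return self.up.backward(du), (dskip if self.cskip else None)

    def params(self):
        return self.conv.params() + self.bn.params()

    def state(self):
        return {"conv": self.conv.state(), "bn": self.bn.state()}

    def load_state(self, s):
        self.conv.load_state(s["conv"])
        self.bn.load_state(s["bn"])


class RetinaUnet:
    """Binary U-Net on a residual 18-layer encoder.

    ``forward`` returns per-pixel foreground probabilities; training uses
    ``forward_logits``/``backward``.  ``checkpoint_shapes`` records the
    (C, H, W) of the contract checkpoints from the latest forward pass.
    """

    def __init__(self, spec: SegmentationModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.width
        c1, c2, c3, c4, cd = (spec.base_widths[i] for i in range(5))
        self.stem = nn.Sequential(
            nn.Conv2d(3, w(c1), 7, stride=2, rng=rng, bias=False),
            nn.BatchNorm2d(w(c1)),
            nn.ReLU(),
        )
        self.pool = nn.MaxPool2d()
        self.enc1 = nn.Sequential(
            _ResidualBlock(w(c1), w(c1), 1, rng), _ResidualBlock(w(c1), w(c1), 1, rng)
        )
        self.enc2 = nn.Sequential(
            _ResidualBlock(w(c1), w(c2), 2, rng), _ResidualBlock(w(c2), w(c2), 1, rng)
        )
        self.enc3 = nn.Sequential(
            _ResidualBlock(w(c2), w(c3), 2, rng), _ResidualBlock(w(c3), w(c3), 1, rng)
        )
        self.enc4 = nn.Sequential(
            _ResidualBlock(w(c3), w(c4), 2, rng), _ResidualBlock(w(c4), w(c4), 1, rng)
        )
        self.dec0 = _DecoderStage(w(c4), w(c3), w(c3), rng)
        self.dec1 = _DecoderStage(w(c3), w(c2), w(c2), rng)
        self.dec2 = _DecoderStage(w(c2), w(c1), w(c1), rng)
        self.dec3 = _DecoderStage(w(c1), w(c1), w(cd), rng)
        self.dec4 = _DecoderStage(w(cd), 0, w(cd // 2), rng)
        self.head = nn.Conv2d(w(cd // 2), 1, 1, pad=0, rng=rng)
        self.checkpoint_shapes: dict[str, tuple[int, int, int]] = {}

    def _modules(self):
        return [
            self.stem, self.enc1, self.enc2, self.enc3, self.enc4,
            self.dec0, self.dec1, self.dec2, self.dec3, self.dec4, self.head,
        ]

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        chw = lambda a: tuple(a.shape[1:])
        s = self.stem.forward(x, train)
        self.checkpoint_shapes["stem"] = chw(s)
        p = self.pool.forward(s, train)
        self.checkpoint_shapes["pooled"] = chw(p)
        e1 = self.enc1.forward(p, train)
        e2 = self.enc2.forward(e1, train)
        e3 = self.enc3.forward(e2, train)
        e4 = self.enc4.forward(e3, train)
        self.checkpoint_shapes["encoder_out"] = chw(e4)
        d0 = self.dec0.forward(e4, e3, train)
        self.checkpoint_shapes["decoder_first"] = chw(d0)
        d1 = self.dec1.forward(d0, e2, train)
        d2 = self.dec2.forward(d1, e1, train)
        d3 = self.dec3.forward(d2, s, train)
        d4 = self.dec4.forward(d3, None, train)
        self.checkpoint_shapes["decoder_last"] = chw(d4)
        out = self.head.forward(d4, train)
        self.checkpoint_shapes["head"] = chw(out)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel foreground probability in [0, 1]."""
        return nn.sigmoid(self.forward_logits(x, train=train))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d4 = self.head.backward(dout)
        dd3, _ = self.dec4.backward(d4)
        dd2, dskip_s = self.dec3.backward(dd3)
        dd1, dskip_e1 = self.dec2.backward(dd2)
        dd0, dskip_e2 = self.dec1.backward(dd1)
        de4, dskip_e3 = self.dec0.backward(dd0)
        de3 = self.enc4.backward(de4) + dskip_e3
        de2 = self.enc3.backward(de3) + dskip_e2
        de1 = self.enc2.backward(de2) + dskip_e1
        dp = self.enc1.backward(de1)
        ds = self.pool.backward(dp) + dskip_s
        return self.stem.backward(ds)

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def state(self):
        return [m.state() for m in self._modules()]

    def load_state(self, state):
        for m, s in zip(self._modules(), state):
            m.load_state(s)


def build_retina_unet(spec: SegmentationModelSpec, seed: int = 0) -> RetinaUnet:
    return RetinaUnet(spec, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class SegmentationSample:
    """One training example: image, binary target plane, patient identity."""

    image: FundusImage
    target: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.target = (np.asarray(self.target) > 0).astype(np.uint8)
        if not self.patient_id:
            self.patient_id = self.image.patient_id

    @property
    def polarity(self) -> str:
        return "positive" if self.target.any() else "negative"


@dataclass
class SegTrainConfig:
    seed: int = 0
    learning_rate: float = 1e-2
    batch_size: int = 8
    max_epochs: int = 40
    patience: int = 5


def split_train_val(
    samples: Sequence[SegmentationSample], seed: int, val_fraction: float = 0.2
) -> tuple[list[SegmentationSample], list[SegmentationSample]]:
    """4:1 train/validation split on disjoint patient IDs."""
    patients = sorted({s.patient_id for s in samples})
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_val = max(1, round(val_fraction * len(patients)))
    val_set = set(patients[:n_val])
    train = [s for s in samples if s.patient_id not in val_set]
    val = [s for s in samples if s.patient_id in val_set]
    assert not ({s.patient_id for s in train} & {s.patient_id for s in val})
    return train, val


def _to_batch(
    samples: Sequence[SegmentationSample],
    stats: NormalizationStats,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack(
        [normalize_image(s.image, stats, size).transpose(2, 0, 1) for s in samples]
    )
    ys = np.stack([resize_mask(s.target, size)[None] for s in samples]).astype(
        np.float32
    )
    return xs, ys


def train_segmentation(
    model: RetinaUnet,
    samples: Sequence[SegmentationSample],
    config: SegTrainConfig,
    stats: NormalizationStats | None = None,
) -> tuple[RetinaUnet, list[dict]]:
    """Train one binary network; returns best-validation-loss weights.

    The 4:1 patient-disjoint split, early stopping and all shuffling are
    driven by ``config.seed``, so two runs with equal seeds produce
    identical loss logs.
    """
    if not any(s.target.any() for s in samples):
        raise MaskValidationError(
            f"no positive samples for class {model.spec.target_class!r}; "
            "refusing to train"
        )
    size = model.spec.input_size
    stats = stats or compute_normalization_stats([s.image for s in samples])
    train, val = split_train_val(samples, seed=config.seed)
    xv, yv = _to_batch(val, stats, size)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    log: list[dict] = []
    best_loss, best_state, best_epoch = np.inf, None, -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        tr_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            xb, yb = _to_batch(batch, stats, size)
            logits = model.forward_logits(xb, train=True)
            loss, grad = nn.bce_dice_loss(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            tr_loss += loss * len(batch)
        tr_loss /= len(train)
        val_logits = model.forward_logits(xv, train=False)
        val_loss, _ = nn.bce_dice_loss(val_logits, yv)
        log.append(
            {"epoch": epoch, "train_loss": tr_loss, "val_loss": float(val_loss)}
        )
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    if best_state is not None:
        model.load_state(best_state)
    return model, log


def predict_mask(
    model: RetinaUnet,
    image: FundusImage,
    stats: NormalizationStats,
    threshold: float = 0.5,
) -> np.ndarray:
    """Binarized (0/1) predicted mask at the model's input resolution."""
    x = normalize_image(image, stats, model.spec.input_size).transpose(2, 0, 1)[None]
    prob = model.forward(x, train=False)[0, 0]
    return (prob > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# metrics


def compute_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """|pred & truth| / |pred | truth|; 1.0 when both masks are empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"{pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def compute_lesion_score(iou_train: float, iou_val: float) -> float:
    """Report score: 0.4 * training IoU + 0.6 * validation IoU (6 decimals).

    The heavier weight on validation IoU rewards generalization over fit.
    """
    for v in (iou_train, iou_val):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"IoU {v} outside [0, 1]")
    return round(0.4 * iou_train + 0.6 * iou_val, 6)
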