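"""Diagnosis and grading classifiers.

The diagnosis network follows the nine-stage mobile-inverted-bottleneck
(MBConv) design: a stride-2 stem convolution, seven stages of MBConv
blocks (expansion factor 1 or 6, depthwise kernel 3x3 or 5x5), and a
1x1-conv + global-average-pool + fully-connected softmax head.  Batch
normalization and the swish activation are used throughout.  A width
multiplier (and configurable input resolution) allows desk-scale
training of the exact same topology.

Diagnosis models consume lesion-focused images (blue channel saturated
at lesion pixels); grading models are two-way (early/late) heads
fine-tuned from a trained diagnosis model so that the already-learned
fundus features transfer.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .exceptions import ParameterError, ShapeMismatchError
from .fusion import FundusImage
from .segmentation import _sk_resize

#: Disease classes of the diagnosis head, fixed order.
DIAGNOSIS_CLASSES: tuple[str, ...] = ("GLAU", "AMD", "RVO", "DR", "NORM")

GRADING_CLASSES: tuple[str, ...] = ("early", "late")

#: Nine-stage table: (operator, expansion, kernel, out channels, repeats, stride)
B0_STAGE_TABLE: tuple[tuple, ...] = (
    ("conv", None, 3, 32, 1, 2),
    ("mbconv", 1, 3, 16, 1, 1),
    ("mbconv", 6, 3, 24, 2, 2),
    ("mbconv", 6, 5, 40, 2, 2),
    ("mbconv", 6, 3, 80, 3, 2),
    ("mbconv", 6, 5, 112, 3, 1),
    ("mbconv", 6, 5, 192, 4, 2),
    ("mbconv", 6, 3, 320, 1, 1),
    ("head", None, 1, 1280, 1, 1),
)


@dataclass
class ClassifierSpec:
    num_classes: int = len(DIAGNOSIS_CLASSES)
    width_multiplier: float = 1.0
    input_size: int = 224
    stage_table: tuple[tuple, ...] = B0_STAGE_TABLE

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ParameterError("num_classes must be >= 2")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ParameterError("width multiplier must be in (0, 1]")
        if len(self.stage_table) != 9:
            raise ParameterError("stage table must have exactly 9 stages")
        if self.stage_table[0][0] != "conv" or self.stage_table[-1][0] != "head":
            raise ParameterError(
                "stage 1 must be a standard convolution and stage 9 the "
                "1x1-conv + pooling + fully-connected head"
            )
        for row in self.stage_table[1:-1]:
            if row[0] != "mbconv" or row[1] not in (1, 6) or row[2] not in (3, 5):
                raise ParameterError(f"invalid bottleneck stage {row}")

    def width(self, base: int) -> int:
        return max(1, math.ceil(base * self.width_multiplier))


class _MBConv(nn.Layer):
    """Inverted bottleneck: 1x1 expand -> depthwise -> 1x1 project."""

    def __init__(self, cin, cout, k, stride, expansion, rng):
        mid = cin * expansion
        self.expand = None
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(cin, mid, 1, pad=0, rng=rng, bias=False),
                nn.BatchNorm2d(mid),
                nn.Swish(),
            )
        self.depthwise = nn.Sequential(
            nn.DepthwiseConv2d(mid, k, stride=stride, rng=rng),
            nn.BatchNorm2d(mid),
            nn.Swish(),
        )
        self.project = nn.Sequential(
            nn.Conv2d(mid, cout, 1, pad=0, rng=rng, bias=False),
            nn.BatchNorm2d(cout),
        )
        self.residual = stride == 1 and cin == cout

    def forward(self, x, train=True):
        h = self.expand.forward(x, train) if self.expand is not None else x
        h = self.project.forward(self.depthwise.forward(h, train), train)
        return h + x if self.residual else h

    def backward(self, dout):
        d = self.depthwise.backward(self.project.backward(dout))
        if self.expand is not None:
            d = self.expand.backward(d)
        return d + dout if self.residual else d

    def params(self):
        ps = self.expand.params() if self.expand is not None else []
        return ps + self.depthwise.params() + self.project.params()

    def state(self):
        return {
            "expand": self.expand.state() if self.expand is not None else None,
            "depthwise": self.depthwise.state(),
            "project": self.project.state(),
        }

    def load_state(self, s):
        if self.expand is not None:
            self.expand.load_state(s["expand"])
        self.depthwise.load_state(s["depthwise"])
        self.project.load_state(s["project"])


class Classifier:
    """Nine-stage MBConv classifier; ``predict_proba`` returns softmax scores."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.width
        blocks: list[nn.Layer] = []
        _, _, k0, c0, _, s0 = spec.stage_table[0]
        blocks += [
            nn.Conv2d(3, w(c0), k0, stride=s0, rng=rng, bias=False),
            nn.BatchNorm2d(w(c0)),
            nn.Swish(),
        ]
        cin = w(c0)
        for op, exp, k, cout, repeats, stride in spec.stage_table[1:-1]:
            cout = w(cout)
            for r in range(repeats):
                blocks.append(
                    _MBConv(cin, cout, k, stride if r == 0 else 1, exp, rng)
                )
                cin = cout
        _, _, kh, ch, _, _ = spec.stage_table[-1]
        blocks += [
            nn.Conv2d(cin, w(ch), kh, pad=0, rng=rng, bias=False),
            nn.BatchNorm2d(w(ch)),
            nn.Swish(),
            nn.GlobalAvgPool(),
        ]
        self.features = nn.Sequential(*blocks)
        self.fc = nn.Linear(w(ch), spec.num_classes, rng=rng)

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.fc.forward(self.features.forward(x, train), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities (softmax over the head's logits)."""
        return nn.softmax(self.forward_logits(x, train=train))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.features.backward(self.fc.backward(dout))

    def params(self):
        return self.features.params() + self.fc.params()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def state(self):
        return {"features": self.features.state(), "fc": self.fc.state()}

    def load_state(self, state):
        self.features.load_state(state["features"])
        self.fc.load_state(state["fc"])


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> Classifier:
    return Classifier(spec, seed=seed)


# ---------------------------------------------------------------------------
# records and training


@dataclass
class PredictionRecord:
    """Per-image softmax scores with identity and ground truth."""

    image_id: str
    patient_id: str
    true_label: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if any(v < 0 for v in self.scores.values()) or abs(total - 1.0) > 1e-6:
            raise ParameterError(
                f"scores must be non-negative and sum to 1, got total {total}"
            )


@dataclass
class TrainingConfig:
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 20
    patience: int = 3
    classes: tuple[str, ...] = DIAGNOSIS_CLASSES

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")


@dataclass
class LabelledImage:
    image: FundusImage
    label: str

    @property
    def image_id(self) -> str:
        return self.image.image_id

    @property
    def patient_id(self) -> str:
        return self.image.patient_id


def _prep(img: FundusImage, size: int) -> np.ndarray:
    arr = img.pixels.astype(np.float32)
    if arr.shape[:2] != (size, size):
        arr = _sk_resize(
            arr, (size, size), order=1, preserve_range=True, anti_aliasing=False
        )
    return ((arr / 255.0 - 0.5) / 0.25).transpose(2, 0, 1).astype(np.float32)


def _check_disjoint(*splits: Sequence[LabelledImage]) -> None:
    seen: set[str] = set()
    for split in splits:
        ids = {s.patient_id for s in split}
        if ids & seen:
            raise ParameterError(
                f"patient IDs overlap across splits: {sorted(ids & seen)[:5]}"
            )
        seen |= ids


def split_dataset_by_patient(
    samples: Sequence[LabelledImage], seed: int, ratios=(0.7, 0.1, 0.2)
) -> tuple[list[LabelledImage], list[LabelledImage], list[LabelledImage]]:
    """Patient-level 7:1:2 split; a patient's images never straddle splits."""
    patients = sorted({s.patient_id for s in samples})
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n = len(patients)
    n_train = round(ratios[0] * n)
    n_val = max(1, round(ratios[1] * n))
    train_p = set(patients[:n_train])
    val_p = set(patients[n_train : n_train + n_val])
    out = (
        [s for s in samples if s.patient_id in train_p],
        [s for s in samples if s.patient_id in val_p],
        [s for s in samples if s.patient_id not in train_p | val_p],
    )
    _check_disjoint(*out)
    return out


def train_diagnosis(
    model: Classifier,
    splits: tuple[
        Sequence[LabelledImage], Sequence[LabelledImage], Sequence[LabelledImage]
    ],
    config: TrainingConfig,
) -> tuple[Classifier, list[dict]]:
    """Train on a patient-disjoint (train, validation, test) triple.

    Stops once validation loss has not improved for ``config.patience``
    epochs and restores the best-validation-loss weights.  Deterministic
    for a given seed.
    """
    train, val, _test = splits
    _check_disjoint(*splits)
    label_to_idx = {c: i for i, c in enumerate(config.classes)}
    size = model.spec.input_size
    xv = np.stack([_prep(s.image, size) for s in val])
    yv = np.array([label_to_idx[s.label] for s in val])
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    log: list[dict] = []
    best_loss, best_state, best_epoch = np.inf, None, -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        tr_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            xb = np.stack([_prep(s.image, size) for s in batch])
            yb = np.array([label_to_idx[s.label] for s in batch])
            logits = model.forward_logits(xb, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            tr_loss += loss * len(batch)
        tr_loss /= len(train)
        val_loss = _eval_loss(model, xv, yv, config.batch_size)
        log.append(
            {"epoch": epoch, "train_loss": tr_loss, "val_loss": val_loss}
        )
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    if best_state is not None:
        model.load_state(best_state)
    return model, log


def _eval_loss(model: Classifier, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total = 0.0
    for start in range(0, len(x), batch):
        logits = model.forward_logits(x[start : start + batch], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[start : start + batch])
        total += loss * len(logits)
    return total / len(x)


def fine_tune_grading(
    base_model: Classifier,
    splits: tuple[
        Sequence[LabelledImage], Sequence[LabelledImage], Sequence[LabelledImage]
    ],
    config: TrainingConfig | None = None,
) -> tuple[Classifier, list[dict]]:
    """Two-way (early/late) grading head fine-tuned from a diagnosis model.

    All feature weights are inherited from the base model; only the head
    is re-initialized, so the grading task starts from already-learned
    fundus representations.
    """
    config = config or TrainingConfig(classes=GRADING_CLASSES)
    labels = {s.label for split in splits for s in split}
    if labels - set(GRADING_CLASSES):
        raise ParameterError(
            f"grading labels must be within {GRADING_CLASSES}, got {sorted(labels)}"
        )
    if tuple(config.classes) != GRADING_CLASSES:
        config = dataclasses.replace(config, classes=GRADING_CLASSES)
    spec = copy.deepcopy(base_model.spec)
    spec.num_classes = 2
    model = Classifier(spec, seed=config.seed)
    model.features.load_state(base_model.features.state())
    return train_diagnosis(model, splits, config)


def predict_proba(
    model: Classifier,
    samples: Sequence[LabelledImage],
    classes: Sequence[str] | None = None,
    batch_size: int = 16,
) -> list[PredictionRecord]:
    """One softmax record per image (batched inference)."""
    classes = tuple(classes or DIAGNOSIS_CLASSES[: model.spec.num_classes])
    if len(classes) != model.spec.num_classes:
        raise ShapeMismatchError(
            f"{len(classes)} class names for a {model.spec.num_classes}-way head"
        )
    records: list[PredictionRecord] = []
    size = model.spec.input_size
    for start in range(0, len(samples), batch_size):
        batch = samples[start : start + batch_size]
        x = np.stack([_prep(s.image, size) for s in batch])
        probs = model.forward(x, train=False)
        probs = probs / probs.sum(axis=1, keepdims=True)
        for s, p in zip(batch, probs):
            records.append(
                PredictionRecord(
                    image_id=s.image_id,
                    patient_id=s.patient_id,
                    true_label=s.label,
                    scores={c: float(v) for c, v in zip(classes, p)},
                )
            )
    return records
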