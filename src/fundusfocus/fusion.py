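"""Lesion-attention compositing.

A lesion-focused image is the original RGB fundus photograph with its blue
channel saturated (set to 255) at every pixel covered by a selected lesion
or anatomy mask, restricted to the camera's circular field of view.  The
red and green channels pass through untouched — equivalent to collapsing
the selected mask planes through a fixed-weight 3x1x1 convolution whose
red/green kernels are zero, thresholding, and compositing the binary map
into the blue plane with bitwise operations.

The composition is deterministic given (image, registry version, channel
set, threshold), so results are memoised by a content-addressed cache.
"""

from __future__ import annotations

import hashlib
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from PIL import Image

from .bitmap import ChannelRegistry, MaskStack, canonical_registry
from .exceptions import ParameterError, ShapeMismatchError

logger = logging.getLogger(__name__)

#: Anatomy/lesion classes highlighted by default when building the
#: classifier's attention input (12 classes).
DEFAULT_ATTENTION_CLASSES: tuple[str, ...] = (
    "optic cup",
    "optic disc",
    "macula",
    "hemorrhage",
    "cotton wool spots",
    "preretinal fibrosis",
    "atrophic arc",
    "choroidal atrophy",
    "choroidal neovascularization",
    "exudation",
    "macular atrophy",
    "leopard fundus",
)

DEFAULT_FOV_THRESHOLD = 10


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph with identity metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ShapeMismatchError(
                f"expected (H, W, 3) pixels, got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def select_attention_channels(
    registry: ChannelRegistry, names: Iterable[str] | None = None
) -> frozenset[int]:
    """Resolve class names (default: the standard attention set) to indices."""
    if names is None:
        names = DEFAULT_ATTENTION_CLASSES
    return frozenset(registry.index_of(n) for n in names)


def collapse_channels(stack: MaskStack, channels: Iterable[int]) -> np.ndarray:
    """OR the selected planes into one binary map scaled to {0, 255}.

    Equivalent to a fixed-weight 1x1 convolution over the selected planes
    followed by a >0 threshold.
    """
    channels = sorted(set(int(c) for c in channels))
    for c in channels:
        if not 0 <= c < stack.planes.shape[0]:
            raise ParameterError(f"channel {c} outside [0, 31]")
    if not channels:
        return np.zeros((stack.height, stack.width), np.uint8)
    combined = stack.planes[channels].any(axis=0)
    return combined.astype(np.uint8) * np.uint8(255)


def threshold_activation(field_: np.ndarray, t: int) -> np.ndarray:
    """Binarize a single-channel 8-bit field: 255 where value > t, else 0."""
    if not 0 <= int(t) <= 255:
        raise ParameterError(f"threshold {t} outside [0, 255]")
    field_ = np.asarray(field_)
    return (field_ > t).astype(np.uint8) * np.uint8(255)


def compose_lesion_focused(
    img: FundusImage,
    fusion_map: np.ndarray,
    fov_threshold: int = DEFAULT_FOV_THRESHOLD,
) -> FundusImage:
    """Saturate the blue channel at lesion pixels inside the field of view.

    The field of view is wherever any RGB channel exceeds ``fov_threshold``
    (the circular retinal area; the camera background is black).  Within it,
    lesion pixels get B=255 via (B AND NOT L) OR L; outside it the image is
    untouched.  R and G always pass through.
    """
    fusion_map = np.asarray(fusion_map)
    if fusion_map.shape != img.pixels.shape[:2]:
        raise ShapeMismatchError(
            f"fusion map {fusion_map.shape} vs image {img.pixels.shape[:2]}"
        )
    fov = threshold_activation(img.pixels.max(axis=2), fov_threshold)
    effective = fusion_map & fov
    out = img.pixels.copy()
    blue = out[:, :, 2]
    out[:, :, 2] = (blue & ~effective) | effective
    return FundusImage(
        pixels=out, image_id=img.image_id, patient_id=img.patient_id
    )


def lesion_focused_from_stack(
    img: FundusImage,
    stack: MaskStack,
    channel_names: Iterable[str] | None = None,
    fov_threshold: int = DEFAULT_FOV_THRESHOLD,
) -> FundusImage:
    """Full attention pipeline: select channels, collapse, composite."""
    channels = select_attention_channels(stack.registry, channel_names)
    return compose_lesion_focused(
        img, collapse_channels(stack, channels), fov_threshold
    )


@dataclass(frozen=True)
class FusionCacheKey:
    """Identity of one composited output (equal keys => identical bytes)."""

    image_id: str
    registry_version: str
    channels: frozenset[int]
    fov_threshold: int

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.image_id.encode())
        h.update(self.registry_version.encode())
        h.update(",".join(map(str, sorted(self.channels))).encode())
        h.update(str(self.fov_threshold).encode())
        return h.hexdigest()


@dataclass
class FusionCache:
    """Content-addressed memoisation of composited images.

    An in-memory LRU front backed (optionally) by PNG files in a cache
    directory.  A corrupted cache file is recomputed and overwritten with
    a logged warning.
    """

    directory: Path | None = None
    max_memory_items: int = 256
    hits: int = 0
    misses: int = 0
    _memory: OrderedDict = field(default_factory=OrderedDict, repr=False)

    def __post_init__(self) -> None:
        if self.directory is not None:
            self.directory = Path(self.directory)
            self.directory.mkdir(parents=True, exist_ok=True)

    def get_or_compute(
        self, key: FusionCacheKey, producer: Callable[[], FundusImage]
    ) -> FundusImage:
        digest = key.digest()
        if digest in self._memory:
            self.hits += 1
            self._memory.move_to_end(digest)
            return self._memory[digest]
        if self.directory is not None:
            path = self.directory / f"{digest}.png"
            if path.exists():
                try:
                    with Image.open(path) as im:
                        pixels = np.asarray(im.convert("RGB"))
                    self.hits += 1
                    img = FundusImage(pixels=pixels, image_id=key.image_id)
                    self._remember(digest, img)
                    return img
                except Exception:  # corrupted cache entry
                    logger.warning(
                        "corrupted fusion cache entry %s; recomputing", path
                    )
        self.misses += 1
        img = producer()
        self._remember(digest, img)
        if self.directory is not None:
            Image.fromarray(img.pixels, mode="RGB").save(
                self.directory / f"{digest}.png", format="PNG"
            )
        return img

    def _remember(self, digest: str, img: FundusImage) -> None:
        self._memory[digest] = img
        self._memory.move_to_end(digest)
        while len(self._memory) > self.max_memory_items:
            self._memory.popitem(last=False)

    @property
    def hit_rate(self) -> float:
        total = self.hits + self.misses
        return self.hits / total if total else 0.0


def cached_fusion(
    cache: FusionCache,
    key: FusionCacheKey,
    producer: Callable[[], FundusImage],
) -> FundusImage:
    """Memoised wrapper around a deterministic fusion producer."""
    return cache.get_or_compute(key, producer)
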