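"""Bit-packed storage of multi-channel binary lesion masks.

Up to 32 aligned binary mask planes are packed, 8 per byte, into the four
8-bit channels of an RGBA image and written as an ordinary PNG.  Plane ``i``
occupies bit ``i mod 8`` (least-significant bit first) of channel
``i // 8`` (R, G, B, A in that order):

    R = sum_{i=0..7}   2^i        * mask_i
    G = sum_{i=8..15}  2^(i-8)    * mask_i
    B = sum_{i=16..23} 2^(i-16)   * mask_i
    A = sum_{i=24..31} 2^(i-24)   * mask_i

Decoding extracts ``mask_i = floor(channel / 2^(i mod 8)) mod 2``.  The
round trip is exact, and PNG's lossless zlib compression makes sparse
mask stacks dramatically smaller than raw float serialization (a
512x512x32 stack is 32 MiB as raw float32 but under 2 KB as an all-zero
packed PNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

from .exceptions import (
    FormatError,
    MaskValidationError,
    RegistryLookupError,
    ShapeMismatchError,
)

N_CHANNELS = 32

#: Canonical anatomy/lesion classes, in fixed registry order (indices 0-19).
#: Indices 20-31 are reserved and always decode to all-zero planes.
CANONICAL_CLASSES: tuple[str, ...] = (
    "optic cup",
    "optic disc",
    "retinal vessel",
    "macula",
    "hemorrhage",
    "cotton wool spots",
    "drusen",
    "atrophic arc",
    "choroidal atrophy",
    "choroidal neovascularization",
    "exudation",
    "macular degeneration",
    "geographic atrophy",
    "retinal nerve fiber layer defects",
    "retinal defect",
    "sclera exposure",
    "tessellated fundus",
    "retinal neovascularization",
    "vitreous hemorrhage",
    "retinal detachment",
)

#: Synonyms that appear in clinical usage, mapped onto canonical names.
#: "preretinal fibrosis" is grouped with retinal neovascularization because
#: clinical staging treats fibrovascular proliferation and new vessels as
#: one late-stage signature.
CLASS_ALIASES: Mapping[str, str] = {
    "optic disk": "optic disc",
    "macular": "macula",
    "cotton-wool spot": "cotton wool spots",
    "cotton wool spot": "cotton wool spots",
    "atrophic crescent": "atrophic arc",
    "macular atrophy": "macular degeneration",
    "leopard fundus": "tessellated fundus",
    "tessellation": "tessellated fundus",
    "tessellated retina": "tessellated fundus",
    "scleral show": "sclera exposure",
    "sclera show": "sclera exposure",
    "preretinal fibrosis": "retinal neovascularization",
    "neovessels elsewhere": "retinal neovascularization",
    "rnfl defects": "retinal nerve fiber layer defects",
}


@dataclass(frozen=True)
class ChannelRegistry:
    """Ordered mapping from class names to bit-plane indices in [0, 31]."""

    entries: tuple[tuple[str, int], ...]
    version: str = "1"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        idxs = [i for _, i in self.entries]
        if len(set(names)) != len(names) or any(not n for n in names):
            raise MaskValidationError("class names must be unique and non-empty")
        if len(set(idxs)) != len(idxs):
            raise MaskValidationError("channel indices must be unique")
        for i in idxs:
            if not 0 <= i < N_CHANNELS:
                raise MaskValidationError(f"channel index {i} outside [0, 31]")

    def index_of(self, name: str) -> int:
        key = name.strip().lower()
        key = CLASS_ALIASES.get(key, key)
        for n, i in self.entries:
            if n == key:
                return i
        raise RegistryLookupError(
            f"unknown class {name!r}; valid names: {[n for n, _ in self.entries]}"
        )

    def name_of(self, index: int) -> str:
        for n, i in self.entries:
            if i == index:
                return n
        raise RegistryLookupError(f"no class at channel {index}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)


def canonical_registry() -> ChannelRegistry:
    """The fixed 20-class registry (optic cup=0 ... retinal detachment=19)."""
    return ChannelRegistry(
        entries=tuple((name, i) for i, name in enumerate(CANONICAL_CLASSES)),
        version="canonical-20",
    )


def _validate_planes(planes: np.ndarray) -> np.ndarray:
    planes = np.asarray(planes)
    if planes.ndim != 3 or planes.shape[0] != N_CHANNELS:
        raise ShapeMismatchError(
            f"expected (32, H, W) planes, got shape {planes.shape}"
        )
    for ch in range(N_CHANNELS):
        vals = np.unique(planes[ch])
        if not np.isin(vals, (0, 1)).all():
            raise MaskValidationError(
                f"channel {ch} contains non-binary values {vals[:8]}"
            )
    return planes.astype(np.uint8)


@dataclass
class MaskStack:
    """32 aligned binary mask planes plus the registry that names them."""

    planes: np.ndarray  # (32, H, W) uint8 in {0, 1}
    registry: ChannelRegistry = field(default_factory=canonical_registry)

    def __post_init__(self) -> None:
        self.planes = _validate_planes(self.planes)

    @classmethod
    def zeros(
        cls, height: int, width: int, registry: ChannelRegistry | None = None
    ) -> "MaskStack":
        return cls(
            planes=np.zeros((N_CHANNELS, height, width), np.uint8),
            registry=registry or canonical_registry(),
        )

    @classmethod
    def from_class_masks(
        cls,
        masks: Mapping[str, np.ndarray],
        registry: ChannelRegistry | None = None,
    ) -> "MaskStack":
        """Assemble a stack from named binary masks; absent classes are zero."""
        registry = registry or canonical_registry()
        shapes = {m.shape for m in masks.values()}
        if len(shapes) > 1:
            raise ShapeMismatchError(f"mask shapes differ: {sorted(shapes)}")
        if not masks:
            raise MaskValidationError("at least one mask required")
        h, w = next(iter(shapes))
        planes = np.zeros((N_CHANNELS, h, w), np.uint8)
        for name, mask in masks.items():
            planes[registry.index_of(name)] = (np.asarray(mask) > 0).astype(np.uint8)
        return cls(planes=planes, registry=registry)

    @property
    def height(self) -> int:
        return self.planes.shape[1]

    @property
    def width(self) -> int:
        return self.planes.shape[2]

    def plane(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.registry.index_of(name_or_index)
        return self.planes[name_or_index]

    def foreground_counts(self) -> dict[str, int]:
        return {
            name: int(self.planes[i].sum()) for name, i in self.registry.entries
        }

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MaskStack) and np.array_equal(
            self.planes, other.planes
        )


@dataclass
class BitmapPng:
    """The packed 4-channel (R, G, B, A) 8-bit representation of a MaskStack."""

    channels: np.ndarray  # (H, W, 4) uint8

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[2] != 4:
            raise FormatError(
                f"expected (H, W, 4) channels, got shape {self.channels.shape}"
            )
        if self.channels.dtype != np.uint8:
            if self.channels.min() < 0 or self.channels.max() > 255:
                raise FormatError("channel values outside [0, 255]")
            self.channels = self.channels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.channels.shape[0]

    @property
    def width(self) -> int:
        return self.channels.shape[1]


_BIT_WEIGHTS = (1 << np.arange(8, dtype=np.uint16))  # LSB-first


def encode_bitmap(stack: MaskStack) -> BitmapPng:
    """Pack 32 binary planes into 4 bytes per pixel (plane 8k = LSB of byte k)."""
    grouped = stack.planes.reshape(4, 8, stack.height, stack.width)
    packed = (grouped.astype(np.uint16) * _BIT_WEIGHTS[None, :, None, None]).sum(
        axis=1
    )
    return BitmapPng(channels=packed.astype(np.uint8).transpose(1, 2, 0))


def decode_bitmap(
    img: BitmapPng, registry: ChannelRegistry | None = None
) -> MaskStack:
    """Unpack 4 bytes per pixel back into 32 binary planes."""
    chans = img.channels.transpose(2, 0, 1)  # (4, H, W)
    planes = (
        (chans[:, None, :, :] >> np.arange(8, dtype=np.uint8)[None, :, None, None])
        & 1
    ).reshape(N_CHANNELS, img.height, img.width)
    return MaskStack(planes=planes, registry=registry or canonical_registry())


def write_bitmap_png(img: BitmapPng, path: str | Path) -> Path:
    """Write the packed image as a standard 8-bit RGBA PNG (lossless)."""
    path = Path(path)
    Image.fromarray(img.channels, mode="RGBA").save(path, format="PNG")
    return path


def read_bitmap_png(path: str | Path) -> BitmapPng:
    path = Path(path)
    with Image.open(path) as im:
        if im.format != "PNG":
            raise FormatError(f"{path} is not a PNG (detected {im.format})")
        if im.mode != "RGBA":
            raise FormatError(
                f"{path} is not an RGBA PNG (detected color mode {im.mode})"
            )
        return BitmapPng(channels=np.asarray(im))


def export_class_masks(
    stack: MaskStack, outdir: str | Path, names: Iterable[str] | None = None
) -> list[Path]:
    """Write each (named) plane as an 8-bit grayscale PNG with values 0/255."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(names) if names is not None else list(stack.registry.names)
    written = []
    for name in names:
        arr = stack.plane(name) * np.uint8(255)
        p = outdir / f"{name.replace(' ', '_')}.png"
        Image.fromarray(arr, mode="L").save(p, format="PNG")
        written.append(p)
    return written


def import_class_masks(
    paths: Mapping[str, str | Path], registry: ChannelRegistry | None = None
) -> MaskStack:
    """Assemble a stack from per-class grayscale PNGs (any non-zero = 1)."""
    masks = {}
    for name, p in paths.items():
        with Image.open(p) as im:
            masks[name] = (np.asarray(im.convert("L")) > 0).astype(np.uint8)
    return MaskStack.from_class_masks(masks, registry=registry)


def raw_float_nbytes(height: int, width: int, channels: int = N_CHANNELS) -> int:
    """Size in bytes of the naive float32 serialization of a mask stack."""
    return height * width * channels * 4
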