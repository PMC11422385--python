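"""Synthetic fundus phantoms with paired ground-truth lesion masks.

Generates the geometry a fundus photograph shows — a circular field of
view on black background, a bright optic disc containing a brighter cup,
a darker macula, and branching vessels radiating from the disc — plus
class-specific lesion signatures (glaucomatous cup enlargement, macular
drusen/exudates, sectoral flame hemorrhages, scattered retinopathy dots
and neovessel curls).  Every rendered structure is simultaneously drawn
into the matching mask channel, so segmentation, fusion and
classification can all be exercised without any real data.

The phantoms are deliberately cartoon-like: intensity statistics,
camera artefacts and anatomical variation of real photographs are not
modelled.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line

from .bitmap import MaskStack, canonical_registry, encode_bitmap, write_bitmap_png
from .exceptions import ConfigError, ParameterError
from .fusion import FundusImage

DISEASES = ("GLAU", "AMD", "RVO", "DR", "NORM")
GRADES = ("early", "late")


@dataclass
class SyntheticFundusConfig:
    size: int = 256
    fov_radius_frac: float = 0.48
    disc_center_frac: tuple[float, float] = (0.5, 0.72)  # (row, col)
    disc_radius_frac: float = 0.11
    cup_to_disc_ratio: float = 0.4
    macula_center_frac: tuple[float, float] = (0.5, 0.34)
    macula_radius_frac: float = 0.07
    n_vessels: int = 6
    vessel_tortuosity: float = 0.35
    noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cup_to_disc_ratio <= 1.0:
            raise ConfigError("cup-to-disc ratio must be in [0, 1]")
        for cy, cx in (self.disc_center_frac, self.macula_center_frac):
            r = np.hypot(cy - 0.5, cx - 0.5)
            if r + self.disc_radius_frac > self.fov_radius_frac + 1e-9:
                raise ConfigError("geometry extends outside the field of view")


def _fov_mask(size: int, frac: float) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= (frac * size) ** 2


def generate_fundus(
    config: SyntheticFundusConfig, seed: int = 0
) -> tuple[FundusImage, MaskStack]:
    """Render one healthy phantom and its anatomy mask channels."""
    rng = np.random.default_rng(seed)
    s = config.size
    img = np.zeros((s, s, 3), np.float32)
    fov = _fov_mask(s, config.fov_radius_frac)

    # retinal background with a mild radial falloff
    yy, xx = np.mgrid[:s, :s]
    c = (s - 1) / 2.0
    falloff = 1.0 - 0.25 * ((yy - c) ** 2 + (xx - c) ** 2) / (c**2 + 1e-9)
    base = np.array([185.0, 92.0, 38.0])
    img[fov] = base * falloff[fov][:, None]

    stack = MaskStack.zeros(s, s)
    reg = stack.registry

    # optic disc (bright ellipse) with inner cup
    dcy, dcx = (np.array(config.disc_center_frac) * s).astype(int)
    dr = config.disc_radius_frac * s
    rr, cc = _draw_ellipse(dcy, dcx, dr, 0.9 * dr, shape=(s, s))
    img[rr, cc] = np.array([235.0, 205.0, 130.0])
    stack.planes[reg.index_of("optic disc"), rr, cc] = 1
    cup_r = config.cup_to_disc_ratio * dr
    if cup_r >= 0.5:
        rr, cc = _draw_ellipse(dcy, dcx, cup_r, 0.9 * cup_r, shape=(s, s))
        img[rr, cc] = np.array([252.0, 235.0, 170.0])
        stack.planes[reg.index_of("optic cup"), rr, cc] = 1

    # macula (darker disk)
    mcy, mcx = (np.array(config.macula_center_frac) * s).astype(int)
    mr = max(2, int(config.macula_radius_frac * s))
    rr, cc = _draw_disk((mcy, mcx), mr, shape=(s, s))
    img[rr, cc] *= 0.55
    stack.planes[reg.index_of("macula"), rr, cc] = 1

    # vessels: tortuous random walks leaving the disc rim outward
    vessel_plane = stack.planes[reg.index_of("retinal vessel")]
    for v in range(config.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        y = float(dcy) + 1.05 * dr * np.sin(ang)
        x = float(dcx) + 1.05 * dr * np.cos(ang)
        for _ in range(int(1.4 * s)):
            ang += rng.normal(0.0, config.vessel_tortuosity)
            ny, nx = y + 1.6 * np.sin(ang), x + 1.6 * np.cos(ang)
            if not (0 <= ny < s and 0 <= nx < s) or not fov[int(ny), int(nx)]:
                break
            rr, cc = _draw_line(int(y), int(x), int(ny), int(nx))
            img[rr, cc] = np.array([120.0, 35.0, 25.0])
            vessel_plane[rr, cc] = 1
            y, x = ny, nx

    if config.noise_sigma > 0:
        img[fov] += rng.normal(0.0, config.noise_sigma, img[fov].shape)
    img[~fov] = 0.0
    # masks only exist inside the field of view
    stack.planes &= fov[None].astype(np.uint8)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels), stack


def _blob(rng, center, radius, shape):
    cy = center[0] + rng.normal(0, 0.5)
    cx = center[1] + rng.normal(0, 0.5)
    return _draw_disk((cy, cx), max(1.0, radius), shape=shape)


def add_disease_signature(
    image: FundusImage,
    stack: MaskStack,
    disease: str,
    grade: str | None = "early",
    seed: int = 0,
    config: SyntheticFundusConfig | None = None,
    render_into_image: bool = True,
) -> tuple[FundusImage, MaskStack]:
    """Render a disease's lesions into the image and its mask channels.

    Grade controls lesion burden monotonically: for the same seed the
    late-grade rendering draws the early lesions first and then adds
    more, so late always has at least as many lesion pixels.  With
    ``render_into_image=False`` only the mask channels are touched —
    useful for cohorts whose class signal lives exclusively in the
    masks.
    """
    if disease not in DISEASES:
        raise ParameterError(f"unknown disease {disease!r}; expected {DISEASES}")
    if disease != "NORM" and grade not in GRADES:
        raise ParameterError(f"grade must be one of {GRADES}, got {grade!r}")
    config = config or SyntheticFundusConfig(size=image.height)
    rng = np.random.default_rng(seed)
    img = image.pixels.astype(np.float32)
    out = MaskStack(planes=stack.planes.copy(), registry=stack.registry)
    reg = out.registry
    s = image.height
    fov = _fov_mask(s, config.fov_radius_frac)
    late = grade == "late"

    def paint(rr, cc, color, channel):
        if render_into_image:
            img[rr, cc] = np.asarray(color, np.float32)
        out.planes[reg.index_of(channel), rr, cc] = 1

    dcy, dcx = (np.array(config.disc_center_frac) * s).astype(int)
    dr = config.disc_radius_frac * s
    mcy, mcx = (np.array(config.macula_center_frac) * s).astype(int)

    if disease == "GLAU":
        # cup-to-disc ratio >= 0.8 (late: near-total excavation)
        cdr = 0.92 if late else 0.82
        rr, cc = _draw_ellipse(dcy, dcx, cdr * dr, 0.9 * cdr * dr, shape=(s, s))
        paint(rr, cc, (252, 238, 178), "optic cup")
    elif disease == "AMD":
        # drusen / exudates within one disc-diameter of the macular center
        n = 9 if late else 4
        spread = 1.6 * dr
        for i in range(n):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, spread)
            center = (mcy + rad * np.sin(ang), mcx + rad * np.cos(ang))
            rr, cc = _blob(rng, center, rng.uniform(0.012, 0.022) * s, (s, s))
            channel = "drusen" if i % 2 else "exudation"
            paint(rr, cc, (250, 238, 180), channel)
    elif disease == "RVO":
        # flame hemorrhages fanning out along an occluded sector
        sector = rng.uniform(0, 2 * np.pi)
        width = 2.4 if late else 1.1
        n = 16 if late else 7
        for _ in range(n):
            ang = sector + rng.uniform(-width / 2, width / 2)
            rad = rng.uniform(1.2 * dr, 0.42 * s)
            y0 = dcy + rad * np.sin(ang)
            x0 = dcx + rad * np.cos(ang)
            y1 = y0 + 0.05 * s * np.sin(ang)
            x1 = x0 + 0.05 * s * np.cos(ang)
            y0, x0, y1, x1 = (int(np.clip(v, 0, s - 1)) for v in (y0, x0, y1, x1))
            rr, cc = _draw_line(y0, x0, y1, x1)
            keep = fov[rr, cc]
            for off in (-1, 0, 1):  # thicken the flame
                oc = np.clip(cc[keep] + off, 0, s - 1)
                paint(rr[keep], oc, (115, 22, 18), "hemorrhage")
        if late:
            for _ in range(3):
                ang = sector + rng.uniform(-width / 2, width / 2)
                rad = rng.uniform(1.4 * dr, 0.38 * s)
                center = (dcy + rad * np.sin(ang), dcx + rad * np.cos(ang))
                rr, cc = _blob(rng, center, 0.02 * s, (s, s))
                paint(rr, cc, (245, 245, 235), "cotton wool spots")
    elif disease == "DR":
        # microaneurysm dots / small hemorrhages; late adds neovessel curls
        n = 26 if late else 9
        for _ in range(n):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.1 * s, 0.42 * s)
            center = (s / 2 + rad * np.sin(ang), s / 2 + rad * np.cos(ang))
            if not fov[int(center[0]) % s, int(center[1]) % s]:
                continue
            rr, cc = _blob(rng, center, rng.uniform(0.006, 0.013) * s, (s, s))
            paint(rr, cc, (110, 20, 16), "hemorrhage")
        if late:
            for _ in range(3):
                ang = rng.uniform(0, 2 * np.pi)
                y, x = dcy + 1.3 * dr * np.sin(ang), dcx + 1.3 * dr * np.cos(ang)
                curl = rng.uniform(0, 2 * np.pi)
                for _ in range(int(0.25 * s)):
                    curl += rng.normal(0.35, 0.15)
                    ny, nx = y + np.sin(curl), x + np.cos(curl)
                    if not (0 <= ny < s and 0 <= nx < s) or not fov[int(ny), int(nx)]:
                        break
                    rr, cc = _draw_line(int(y), int(x), int(ny), int(nx))
                    paint(rr, cc, (150, 40, 60), "retinal neovascularization")
                    y, x = ny, nx
    # NORM: no lesions

    out.planes &= fov[None].astype(np.uint8)
    if render_into_image:
        img[~fov] = 0.0
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return (
        FundusImage(
            pixels=pixels, image_id=image.image_id, patient_id=image.patient_id
        ),
        out,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticImage:
    image: FundusImage
    masks: MaskStack


@dataclass
class SyntheticPatient:
    patient_id: str
    disease: str
    grade: str | None
    images: list[SyntheticImage]


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    class_mix: dict[str, float]
    seed: int

    def all_images(self) -> list[tuple[SyntheticPatient, SyntheticImage]]:
        return [(p, im) for p in self.patients for im in p.images]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for i, im in enumerate(p.images):
                rows.append(
                    {
                        "image_id": im.image.image_id,
                        "patient_id": p.patient_id,
                        "disease": p.disease,
                        "grade": p.grade or "",
                    }
                )
        return pd.DataFrame(rows)


def generate_cohort(
    n_patients: int,
    class_mix: dict[str, float] | None = None,
    images_per_patient: int = 1,
    seed: int = 0,
    size: int = 256,
    render_into_image: bool = True,
    config: SyntheticFundusConfig | None = None,
) -> SyntheticCohort:
    """Patient-structured cohort; all of a patient's images share one label."""
    class_mix = class_mix or {d: 1.0 / len(DISEASES) for d in DISEASES}
    if abs(sum(class_mix.values()) - 1.0) > 1e-6:
        raise ParameterError("class mix must sum to 1")
    active = [d for d, w in class_mix.items() if w > 0]
    for d in active:
        if d not in DISEASES:
            raise ParameterError(f"unknown disease {d!r}")
    if n_patients < len(active):
        raise ParameterError(
            f"{n_patients} patients cannot cover {len(active)} classes"
        )
    rng = np.random.default_rng(seed)
    diseases = rng.choice(
        active, size=n_patients, p=[class_mix[d] / sum(class_mix[d] for d in active) for d in active]
    )
    # guarantee every requested class appears at least once
    for i, d in enumerate(active):
        if d not in diseases:
            diseases[i] = d
    patients = []
    base_config = config or SyntheticFundusConfig(size=size)
    for i in range(n_patients):
        disease = str(diseases[i])
        grade = None if disease == "NORM" else str(rng.choice(GRADES))
        pid = f"P{i:05d}"
        images = []
        for j in range(images_per_patient):
            img_seed = int(rng.integers(0, 2**31 - 1))
            img, stack = generate_fundus(base_config, seed=img_seed)
            img.image_id = f"{pid}_I{j}"
            img.patient_id = pid
            img, stack = add_disease_signature(
                img,
                stack,
                disease,
                grade,
                seed=img_seed + 1,
                config=base_config,
                render_into_image=render_into_image,
            )
            images.append(SyntheticImage(image=img, masks=stack))
        patients.append(
            SyntheticPatient(
                patient_id=pid, disease=disease, grade=grade, images=images
            )
        )
    return SyntheticCohort(patients=patients, class_mix=dict(class_mix), seed=seed)


def split_by_patient(
    cohort: SyntheticCohort,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """7:1:2 patient-level split into train/validation/test manifests."""
    if len(cohort.patients) < 10:
        raise ParameterError("need at least 10 patients to split 7:1:2")
    ids = [p.patient_id for p in cohort.patients]
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = round(ratios[0] * n)
    n_val = max(1, round(ratios[1] * n))
    groups = {
        "train": set(ids[:n_train]),
        "val": set(ids[n_train : n_train + n_val]),
        "test": set(ids[n_train + n_val :]),
    }
    manifest = cohort.manifest()
    out = []
    for name in ("train", "val", "test"):
        sub = manifest[manifest["patient_id"].isin(groups[name])].copy()
        sub["split"] = name
        out.append(sub.reset_index(drop=True))
    assert not (groups["train"] & groups["val"])
    assert not (groups["train"] & groups["test"])
    assert not (groups["val"] & groups["test"])
    return tuple(out)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write images as RGB PNGs, masks as packed RGBA PNGs, plus manifest."""
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        for im in p.images:
            Image.fromarray(im.image.pixels, "RGB").save(
                outdir / "images" / f"{im.image.image_id}.png"
            )
            write_bitmap_png(
                encode_bitmap(im.masks),
                outdir / "masks" / f"{im.image.image_id}_masks.png",
            )
    cohort.manifest().to_csv(outdir / "manifest.csv", index=False)
    return outdir
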