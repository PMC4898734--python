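"""Seed-reproducible synthetic pollen-like image generation.

Real pollen types photographed under a light microscope differ in outline
(round, elongated, echinate/spiky), exine texture and staining color.  The
generator emulates exactly those axes: each class is a base shape (disk,
ellipse, or a disk with sinusoidal radial spikes), a texture level
(Gaussian intensity noise, optional sinusoidal stripes) and an HSV tint,
with per-image multiplicative jitter on the parameters so classes have
within-class variance.  One object per image on a uniform white
background, matching the segmented-image contract of the loader.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset_io import LabeledImageSet, SegmentedPollenImage, ValidationError

__all__ = [
    "SyntheticClassSpec",
    "generate_shape_mask",
    "render_image",
    "generate_dataset",
    "write_dataset",
    "default_class_specs",
]

DEFAULT_CANVAS = 256
DEFAULT_N_PER_CLASS = 35  # images per pollen type in the emulated study
DEFAULT_JITTER = 0.05


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Parameters defining one synthetic pollen class.

    ``spike_depth`` is the fractional radial dip between spikes (0 = disk);
    ``noise_sigma`` is additive Gaussian intensity noise in gray levels
    (0-255); ``tint`` is the target (hue, saturation, brightness) in [0,1];
    ``jitter`` is the per-image multiplicative parameter noise.
    """

    name: str
    base_shape: str = "disk"  # disk | ellipse | star
    radius: float = 60.0
    axis_ratio: float = 1.0
    spike_count: int = 0
    spike_depth: float = 0.0
    noise_sigma: float = 10.0
    stripe_period: float | None = None
    tint: tuple[float, float, float] = (0.1, 0.6, 0.7)
    jitter: float = DEFAULT_JITTER

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("class name must be non-empty")
        if self.base_shape not in ("disk", "ellipse", "star"):
            raise ValidationError(f"unknown base_shape {self.base_shape!r}")
        if self.radius < 8:
            raise ValidationError("radius must be >= 8 px")
        if not (0 < self.axis_ratio <= 1):
            raise ValidationError("axis_ratio must be in (0, 1]")
        if not (0 <= self.spike_depth < 1):
            raise ValidationError("spike_depth must be in [0, 1)")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")


def generate_shape_mask(
    spec: SyntheticClassSpec,
    canvas: int = DEFAULT_CANVAS,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rasterize one filled shape with seeded parameter jitter.

    A star is a disk whose radius dips sinusoidally between ``spike_count``
    spikes: r(theta) = R * (1 - depth * (1 - cos(n*theta)) / 2), so the
    outer radius (and hence the Feret length) is preserved at the spike
    tips while the area shrinks with depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    j = lambda: 1.0 + spec.jitter * rng.standard_normal()  # noqa: E731
    radius = spec.radius * j()
    ratio = min(1.0, max(0.05, spec.axis_ratio * j()))
    depth = min(0.95, max(0.0, spec.spike_depth * (j() if spec.spike_depth else 1)))
    angle0 = rng.uniform(0, 2 * np.pi)  # random shape orientation
    if radius * 2 >= canvas - 4:
        raise ValidationError(
            f"shape of radius {radius:.0f} exceeds canvas {canvas}"
        )
    cy = cx = canvas / 2.0
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx) - angle0
    # rotated elliptical radius
    er = np.hypot(np.cos(theta), np.sin(theta) / ratio)
    rr = np.hypot(dy, dx) * er
    if spec.base_shape == "star" and spec.spike_count > 0:
        boundary = radius * (1 - depth * (1 - np.cos(spec.spike_count * theta)) / 2)
    else:
        boundary = np.full_like(rr, radius)
    mask = rr <= boundary
    if not mask.any():
        raise ValidationError("degenerate shape produced an empty mask")
    return mask


def _tint_to_rgb(tint: tuple[float, float, float]) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb(*tint)
    return np.array([r, g, b]) * 255.0


def render_image(
    mask: np.ndarray,
    spec: SyntheticClassSpec,
    seed: int | np.random.Generator = 0,
) -> SegmentedPollenImage:
    """Render a mask as an RGB pollen image on a white background.

    The foreground is filled at the tint color; Gaussian intensity noise
    (sigma in gray levels, identical across channels) and an optional
    sinusoidal brightness stripe pattern give the grain GLCM texture and
    gradient structure for the interest-point detector.  Values are
    clipped to [0, 255] after the addition.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    img = np.full((h, w, 3), 255.0)
    img[mask] = _tint_to_rgb(spec.tint)
    if spec.stripe_period:
        yy, xx = np.mgrid[0:h, 0:w]
        phase = rng.uniform(0, 2 * np.pi)
        angle = rng.uniform(0, np.pi)
        coord = yy * np.sin(angle) + xx * np.cos(angle)
        stripes = 30.0 * np.sin(2 * np.pi * coord / spec.stripe_period + phase)
        img[mask] += stripes[mask, None]
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(h, w))
        img[mask] += noise[mask, None]
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return SegmentedPollenImage(
        pixels=pixels, mask=mask, label=spec.name, source_id=""
    )


def generate_dataset(
    specs: list[SyntheticClassSpec],
    n_per_class: int = DEFAULT_N_PER_CLASS,
    canvas: int = DEFAULT_CANVAS,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate ``n_per_class`` seeded variants of every class spec.

    Fully deterministic under (specs, n_per_class, canvas, seed); ordering
    is lexicographic by class name then image index, matching the loader.
    """
    if not specs:
        raise ValidationError("at least one class spec required")
    images: list[SegmentedPollenImage] = []
    ordered = sorted(specs, key=lambda s: s.name)
    class_names = [s.name for s in ordered]
    if len(set(class_names)) != len(class_names):
        raise ValidationError("class spec names must be unique")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(ordered))
    for spec, stream in zip(ordered, streams):
        child_seeds = stream.spawn(n_per_class)
        for i, child in enumerate(child_seeds):
            rng = np.random.default_rng(child)
            mask = generate_shape_mask(spec, canvas, rng)
            img = render_image(mask, spec, rng)
            img.source_id = f"{spec.name}/{spec.name}_{i:03d}"
            images.append(img)
    return LabeledImageSet(images=images, class_names=class_names)


def write_dataset(
    dataset: LabeledImageSet,
    out_dir: str | Path,
    masks_dir: str | Path | None = None,
) -> None:
    """Write a dataset in the directory-per-class layout (PNG).

    When ``masks_dir`` is given, the generator's ground-truth masks are
    stored there in a parallel tree so mask-recovery accuracy stays
    measurable without polluting the image tree.
    """
    out = Path(out_dir)
    for img in dataset.images:
        name = img.source_id.split("/")[-1] or "image"
        cdir = out / img.label
        cdir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img.pixels).save(cdir / f"{name}.png")
        if masks_dir is not None:
            mdir = Path(masks_dir) / img.label
            mdir.mkdir(parents=True, exist_ok=True)
            Image.fromarray((img.mask * 255).astype(np.uint8)).save(
                mdir / f"{name}.png"
            )


def default_class_specs(n_classes: int = 5) -> list[SyntheticClassSpec]:
    """Well-separated class specs covering the shape/texture/color axes.

    Classes cycle through disk / ellipse / star outlines, noise levels and
    hue tints, so any prefix of the list is mutually separable on several
    feature groups at once.
    """
    shapes = [
        ("disk", 1.0, 0, 0.0),
        ("ellipse", 0.5, 0, 0.0),
        ("star", 1.0, 12, 0.4),
        ("ellipse", 0.75, 0, 0.0),
        ("star", 1.0, 6, 0.25),
    ]
    specs = []
    for i in range(n_classes):
        shape, ratio, spikes, depth = shapes[i % len(shapes)]
        hue = (i / max(n_classes, 1)) % 1.0
        noise = 4.0 + 7.0 * (i % 6)
        stripe = None if i % 3 == 0 else 8.0 + 5.0 * (i % 8)
        specs.append(
            SyntheticClassSpec(
                name=f"class_{i:02d}",
                base_shape=shape,
                radius=42.0 + 6.0 * (i % 4),
                axis_ratio=ratio,
                spike_count=spikes,
                spike_depth=depth,
                noise_sigma=noise,
                stripe_period=stripe,
                tint=(hue, 0.5 + 0.12 * (i % 4), 0.5 + 0.1 * (i % 4)),
            )
        )
    return specs
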