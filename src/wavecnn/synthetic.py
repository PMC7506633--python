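"""Seeded synthetic "histology-like" RGB fixtures.

Real histopathology classes differ, among other things, in nuclear density
and in the spatial frequency of tissue texture.  The generator emulates just
those statistical hooks: a base stain color, Poisson-placed dark Gaussian
"nuclei" spots, an oriented sinusoidal texture, and white Gaussian noise,
clipped to [0, 1].  Class separability is therefore carried by multi-scale
texture statistics - exactly the information the wavelet subbands expose -
while nothing about the images is histologically plausible.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; the same seed, spec and size reproduce
byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError


@dataclass(frozen=True)
class TextureClassSpec:
    """Statistical recipe for one image class.

    spot_density is the expected number of nuclei spots per 10^4 pixels;
    texture_freq is in cycles per 100 pixels; colors are RGB in [0, 1].
    """

    class_name: str
    spot_density: float = 10.0
    spot_radius_px: tuple[float, float] = (4.0, 1.0)  # mean, sd
    base_color: tuple[float, float, float] = (0.8, 0.6, 0.75)
    texture_freq: float = 5.0
    texture_amp: float = 0.08
    noise_sd: float = 0.02
    spot_depth: float = 0.45  # peak darkening of a nucleus spot

    def __post_init__(self):
        if self.spot_density < 0 or self.texture_freq < 0 or self.noise_sd < 0:
            raise InputError("densities, frequencies and noise must be nonnegative")
        if self.spot_radius_px[0] <= 0:
            raise InputError("mean spot radius must be positive")
        if not all(0.0 <= v <= 1.0 for v in self.base_color):
            raise InputError("base_color entries must lie in [0, 1]")


# Per-channel weighting of the nucleus darkening: hematoxylin-stained nuclei
# absorb red/green more than blue.
_SPOT_CHANNEL_WEIGHT = np.array([1.0, 0.95, 0.55])


def generate_image(spec: TextureClassSpec, size: tuple[int, int] = (256, 256), seed: int = 0):
    """One synthetic RGB image for a class spec; deterministic in the seed."""
    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise InputError(f"image size must be >= 32 per side, got {(h, w)}")
    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3))
    img[...] = np.asarray(spec.base_color)

    if spec.texture_amp > 0 and spec.texture_freq > 0:
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        carrier = (xx * np.cos(theta) + yy * np.sin(theta)) * (2 * np.pi * spec.texture_freq / 100.0)
        img += (spec.texture_amp * np.sin(carrier + phase))[:, :, None]

    n_spots = rng.poisson(spec.spot_density * h * w / 1e4)
    mean_r, sd_r = spec.spot_radius_px
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        radius = max(float(rng.normal(mean_r, sd_r)), 1.0)
        ext = int(np.ceil(3 * radius))
        y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, h)
        x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))
        img[y0:y1, x0:x1, :] -= spec.spot_depth * blob[:, :, None] * _SPOT_CHANNEL_WEIGHT

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def default_class_specs(n_classes: int = 2) -> list[TextureClassSpec]:
    """Built-in class recipes: a benign/malignant pair or the four-tissue set.

    Classes are graded jointly in texture frequency and nuclear density, the
    axes along which real tissue grades differ most visibly at low
    magnification.
    """
    table = {
        "normal": dict(texture_freq=2.0, spot_density=5.0, spot_radius_px=(4.5, 1.0),
                       base_color=(0.85, 0.7, 0.8)),
        "benign": dict(texture_freq=4.0, spot_density=10.0, spot_radius_px=(4.0, 1.0),
                       base_color=(0.82, 0.64, 0.78)),
        "in_situ": dict(texture_freq=9.0, spot_density=22.0, spot_radius_px=(3.5, 0.8),
                        base_color=(0.76, 0.56, 0.74)),
        "invasive": dict(texture_freq=16.0, spot_density=40.0, spot_radius_px=(3.0, 0.8),
                         base_color=(0.7, 0.5, 0.7)),
    }
    if n_classes == 2:
        names = ["benign", "invasive"]
        rename = {"benign": "benign", "invasive": "malignant"}
    elif n_classes == 4:
        names = list(table)
        rename = {n: n for n in names}
    else:
        raise InputError(f"built-in specs exist for 2 or 4 classes, got {n_classes}")
    return [TextureClassSpec(class_name=rename[n], **table[n]) for n in names]


def generate_dataset(
    class_specs: list[TextureClassSpec],
    n_per_class: int,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
):
    """Balanced labelled image set with per-image child seeds.

    Returns ``(images, labels, manifest)`` where ``images`` is a list of
    (H, W, 3) arrays, ``labels`` the class names, and ``manifest`` a
    DataFrame with one row per image (image_id, class, seed).
    """
    if len(class_specs) < 2:
        raise InputError("need at least 2 classes")
    names = [s.class_name for s in class_specs]
    if len(set(names)) != len(names):
        raise InputError(f"duplicate class names: {names}")
    children = np.random.SeedSequence(seed).spawn(len(class_specs) * n_per_class)
    images, labels, rows = [], [], []
    idx = 0
    for spec in class_specs:
        for i in range(n_per_class):
            child_seed = children[idx]
            img = generate_image(spec, size=size, seed=child_seed)
            image_id = f"{spec.class_name}_{i:04d}"
            images.append(img)
            labels.append(spec.class_name)
            rows.append(
                {"image_id": image_id, "class": spec.class_name,
                 "seed_entropy": str(child_seed.entropy), "index": idx}
            )
            idx += 1
    manifest = pd.DataFrame(rows, columns=["image_id", "class", "seed_entropy", "index"])
    return images, labels, manifest


def write_dataset(images, labels, manifest, out_dir) -> pd.DataFrame:
    """Write PNGs in the ``root/<class>/image.png`` layout plus a CSV manifest."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    paths = []
    for img, label, image_id in zip(images, labels, manifest["image_id"]):
        cls_dir = out / str(label)
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{image_id}.png"
        iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
        paths.append(str(path.relative_to(out)))
    manifest = manifest.assign(file=paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
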