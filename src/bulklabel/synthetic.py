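"""Synthetic ROI images with instance masks and ground-truth class tables.

Real inputs to the labeling engine are pre-cropped regions of interest from
whole-slide images plus an instance segmentation mask (one positive integer id
per object).  This module fabricates such inputs with a *known* class per
object so that every downstream stage — patch extraction, representation
learning, embedding, simulated annotation, efficiency metrics — can be tested
end to end without any external dataset.

Objects are axis-aligned ellipses.  Each class has a base fill color (a hue)
and a sinusoidal texture frequency; a single ``separability`` scalar in
[0, 1] interpolates all class appearance parameters toward a common mean, so
``separability=1`` gives maximally distinct classes and ``separability=0``
makes all classes identically distributed.  Pixel noise is controlled
independently by ``noise_sd``.  Texture is mean-centered over each object's
footprint, so at ``noise_sd=0`` the mean fill color of an object equals its
class base color exactly.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

__all__ = [
    "SyntheticSpec",
    "PackingError",
    "generate_dataset",
    "corrupt_labels",
    "write_dataset",
    "read_dataset",
]

# Appearance constants: the common-mean appearance that all classes collapse
# onto at separability 0, and the amplitude of the sinusoidal fill texture.
_MEAN_COLOR = np.array([0.55, 0.50, 0.60])
_MEAN_FREQ = 0.16  # cycles / pixel
_TEXTURE_AMP = 0.08
_BACKGROUND = 0.82


class PackingError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults generate 10 images of 30 objects each (300 objects total) in
    3 well-separated classes — a desk-scale stand-in for a nuclei/tubule
    labeling task that is easy enough for a small encoder yet not solvable
    from raw pixels alone.
    """

    n_images: int = 10
    image_size: tuple[int, int] = (128, 128)
    n_objects_per_image: int = 30
    n_classes: int = 3
    separability: float = 0.9
    object_radius_range: tuple[int, int] = (5, 9)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if min(self.n_images, self.n_objects_per_image) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.object_radius_range
        if not (0 < lo <= hi):
            raise ValueError("object_radius_range must satisfy 0 < lo <= hi")


def class_appearance(spec: SyntheticSpec, class_id: int) -> tuple[np.ndarray, float]:
    """Base fill color and texture frequency for ``class_id`` (1-based).

    Class base hues are spread evenly on the hue circle; frequencies are
    spread linearly.  Both are interpolated toward the common mean by
    ``1 - separability``.
    """
    k = class_id - 1
    hue = k / spec.n_classes
    base = np.array(colorsys.hsv_to_rgb(hue, 0.65, 0.75))
    freq = 0.08 + 0.16 * (k / max(spec.n_classes - 1, 1))
    s = spec.separability
    color = _MEAN_COLOR + s * (base - _MEAN_COLOR)
    freq = _MEAN_FREQ + s * (freq - _MEAN_FREQ)
    return color, freq


def _place_objects(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[int, int, int, int]]:
    """Rejection-sample non-overlapping ellipse parameters (r, c, rr, rc)."""
    h, w = spec.image_size
    occupied = np.zeros((h, w), dtype=bool)
    placed: list[tuple[int, int, int, int]] = []
    lo, hi = spec.object_radius_range
    for _ in range(spec.n_objects_per_image):
        for _attempt in range(1000):
            rr = int(rng.integers(lo, hi + 1))
            rc = int(rng.integers(lo, hi + 1))
            if 2 * rr + 1 > h or 2 * rc + 1 > w:
                raise PackingError(
                    f"object radius {(rr, rc)} does not fit in image {spec.image_size}"
                )
            r = int(rng.integers(rr, h - rr))
            c = int(rng.integers(rc, w - rc))
            fr, fc = ellipse(r, c, rr, rc, shape=(h, w))
            if not occupied[fr, fc].any():
                occupied[fr, fc] = True
                placed.append((r, c, rr, rc))
                break
        else:
            raise PackingError(
                f"could not place object {len(placed) + 1} of "
                f"{spec.n_objects_per_image} after 1000 attempts; "
                "reduce n_objects_per_image or object radii"
            )
    return placed


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame]:
    """Generate images, instance masks and the ground-truth class table.

    Returns
    -------
    images : list of (H, W, 3) uint8 arrays
    masks : list of (H, W) uint16 arrays, pixel value = instance id (0 = background)
    truth : DataFrame with columns ``image_id, instance_id, class_id``;
        one row per object, ``class_id`` in 1..K.

    The same spec (including seed) always regenerates byte-identical output.

    Raises
    ------
    PackingError
        If the requested object count/radii cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    rows: list[tuple[str, int, int]] = []

    for i in range(spec.n_images):
        image_id = f"img_{i:03d}"
        img = np.full((h, w, 3), _BACKGROUND, dtype=np.float64)
        mask = np.zeros((h, w), dtype=np.uint16)
        placed = _place_objects(spec, rng)
        for inst, (r, c, rr, rc) in enumerate(placed, start=1):
            class_id = int(rng.integers(1, spec.n_classes + 1))
            color, freq = class_appearance(spec, class_id)
            fr, fc = ellipse(r, c, rr, rc, shape=(h, w))
            mask[fr, fc] = inst
            # Sinusoidal texture with per-object random orientation and phase,
            # mean-centered over the footprint so the mean fill color is the
            # class base color exactly.
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(
                2 * np.pi * freq * (fr * np.cos(theta) + fc * np.sin(theta)) + phase
            )
            wave = _TEXTURE_AMP * (wave - wave.mean())
            img[fr, fc] = color + wave[:, None]
            rows.append((image_id, inst, class_id))
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        images.append((np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8))
        masks.append(mask)

    truth = pd.DataFrame(rows, columns=["image_id", "instance_id", "class_id"])
    return images, masks, truth


def corrupt_labels(
    truth: pd.DataFrame, error_rate: float, seed: int
) -> pd.DataFrame:
    """Flip each row's class to a uniformly random *different* class with
    probability ``error_rate`` — a simple model of annotator error."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    out = truth.copy()
    if len(out) == 0 or error_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    k = int(truth["class_id"].max())
    k = max(k, 2)
    flip = rng.random(len(out)) < error_rate
    # Uniform over the K-1 other classes: draw an offset in 1..K-1.
    offsets = rng.integers(1, k, size=len(out))
    new = ((out["class_id"].to_numpy() - 1 + offsets) % k) + 1
    out.loc[flip, "class_id"] = new[flip]
    return out


def write_dataset(
    out_dir: str | Path,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    truth: pd.DataFrame,
) -> None:
    """Write images (8-bit RGB PNG), masks (16-bit PNG) and the truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (img, mask) in enumerate(zip(images, masks)):
        iio.imwrite(out / f"img_{i:03d}.png", img)
        iio.imwrite(out / f"img_{i:03d}_mask.png", mask.astype(np.uint16))
    truth.to_csv(out / "truth.csv", index=False)


def read_dataset(
    in_dir: str | Path,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame]:
    """Inverse of :func:`write_dataset`."""
    src = Path(in_dir)
    images, masks = [], []
    for p in sorted(src.glob("img_*.png")):
        if p.stem.endswith("_mask"):
            continue
        images.append(iio.imread(p))
        masks.append(iio.imread(src / f"{p.stem}_mask.png").astype(np.uint16))
    truth = pd.read_csv(src / "truth.csv")
    return images, masks, truth
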