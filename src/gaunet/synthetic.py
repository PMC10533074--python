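"""Seeded organ-like phantom datasets: bright elliptical blobs on a noisy
background, with paired binary masks and the 80/20 + 10%-validation split.

The phantoms stand in for binary medical segmentation data (lung/liver CT
slices, fluorescence nuclei): each mask is a union of randomly placed,
randomly oriented filled ellipses; the image takes ``foreground_intensity``
on the mask and ``background_intensity`` elsewhere plus clipped Gaussian
noise.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as _ellipse

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "SyntheticConfig",
    "DatasetSplit",
    "generate_dataset",
    "split_dataset",
    "write_dataset",
    "read_dataset",
    "load_split",
]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Phantom generator settings.

    Defaults give 64x64 single-channel images with 2-5 ellipses of semi-axes
    6-16 px, foreground 0.8 on background 0.2, noise sigma 0.05.
    """

    n_images: int = 60
    image_size: int = 64
    channels: int = 1
    blobs_per_image: tuple[int, int] = (2, 5)
    blob_axis_range: tuple[int, int] = (6, 16)
    foreground_intensity: float = 0.8
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ConfigurationError("n_images must be >= 1")
        if self.image_size % 8 != 0:
            raise ConfigurationError(
                f"image_size must be divisible by 8, got {self.image_size}"
            )
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 or 3")
        lo, hi = self.blobs_per_image
        alo, ahi = self.blob_axis_range
        if not (1 <= lo <= hi) or not (1 <= alo <= ahi):
            raise ConfigurationError("blob count/axis ranges must be 1 <= lo <= hi")
        for name in ("foreground_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.foreground_intensity == self.background_intensity:
            raise ConfigurationError("foreground and background intensities must differ")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]


def generate_dataset(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(images, masks)``: float images in [0, 1] of shape
    ``(N, H, W)`` (or ``(N, H, W, 3)``) and uint8 masks ``(N, H, W)``."""
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    shape = (config.n_images, s, s) if config.channels == 1 else (config.n_images, s, s, 3)
    masks = np.zeros((config.n_images, s, s), dtype=np.uint8)
    for i in range(config.n_images):
        n_blobs = int(rng.integers(config.blobs_per_image[0], config.blobs_per_image[1] + 1))
        for _ in range(n_blobs):
            r, c = rng.uniform(0, s, size=2)
            a, b = rng.uniform(config.blob_axis_range[0], config.blob_axis_range[1], size=2)
            angle = rng.uniform(0, np.pi)
            rr, cc = _ellipse(r, c, a, b, shape=(s, s), rotation=angle)
            masks[i, rr, cc] = 1
    base = np.where(
        masks.astype(bool), config.foreground_intensity, config.background_intensity
    )
    if config.channels == 3:
        base = np.repeat(base[..., None], 3, axis=-1)
    noise = rng.normal(0.0, config.noise_sigma, size=shape) if config.noise_sigma > 0 else 0.0
    images = np.clip(base + noise, 0.0, 1.0).astype(np.float32)
    return images, masks


def split_dataset(n: int, seed: int = 0) -> DatasetSplit:
    """Shuffled 80/20 train/test split with 10% of the training portion
    (floored, at least one image) held out for validation."""
    if n < 10:
        raise ConfigurationError(f"need at least 10 images to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = n // 5
    rest = n - n_test
    n_val = max(rest // 10, 1)
    test = tuple(int(i) for i in order[:n_test])
    validation = tuple(int(i) for i in order[n_test : n_test + n_val])
    train = tuple(int(i) for i in order[n_test + n_val :])
    return DatasetSplit(train=train, validation=validation, test=test)


def _stem(i: int) -> str:
    return f"img_{i:03d}"


def write_dataset(
    images: np.ndarray,
    masks: np.ndarray,
    directory: Union[str, Path],
    split: DatasetSplit | None = None,
) -> None:
    """Write 8-bit PNGs under ``images/`` and ``masks/`` (masks as 0/255),
    plus ``split.json`` when a split is given."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    for i, (img, msk) in enumerate(zip(images, masks)):
        img8 = np.clip(np.round(np.asarray(img) * 255), 0, 255).astype(np.uint8)
        iio.imwrite(directory / "images" / f"{_stem(i)}.png", img8)
        iio.imwrite(
            directory / "masks" / f"{_stem(i)}.png",
            (np.asarray(msk) > 0).astype(np.uint8) * 255,
        )
    if split is not None:
        (directory / "split.json").write_text(
            json.dumps(dataclasses.asdict(split), indent=2) + "\n"
        )


def read_dataset(directory: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read a PNG dataset back; images in [0, 1], masks in {0, 1}."""
    directory = Path(directory)
    img_dir, msk_dir = directory / "images", directory / "masks"
    if not img_dir.is_dir() or not msk_dir.is_dir():
        raise IntegrityError(f"{directory} must contain images/ and masks/")
    img_stems = {p.stem for p in img_dir.glob("*.png")}
    msk_stems = {p.stem for p in msk_dir.glob("*.png")}
    if not img_stems:
        raise IntegrityError(f"no PNG images found under {img_dir}")
    if img_stems != msk_stems:
        missing = sorted(img_stems ^ msk_stems)
        raise IntegrityError(f"image/mask stems mismatch, missing pairs for: {missing}")
    images, masks = [], []
    for stem in sorted(img_stems):
        img = np.asarray(iio.imread(img_dir / f"{stem}.png"), dtype=np.float32) / 255.0
        msk = (np.asarray(iio.imread(msk_dir / f"{stem}.png")) > 127).astype(np.uint8)
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)


def load_split(directory: Union[str, Path]) -> DatasetSplit:
    payload = json.loads((Path(directory) / "split.json").read_text())
    return DatasetSplit(
        train=tuple(payload["train"]),
        validation=tuple(payload["validation"]),
        test=tuple(payload["test"]),
    )
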