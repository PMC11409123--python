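"""Synthetic labeled fundus-like images.

Two-class generator: every image carries a radial-gradient disc on a dark
background crossed by vessel-like random-walk curves; the positive class
additionally plants bright exudate-like blobs and dark hemorrhage-like
dots inside the disc.  The bright-blob structure makes the classes
separable by construction, which is what downstream tuning and
cross-validation tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FundusParams:
    size: int = 64
    vessel_count: int = 4
    lesion_count_range: tuple[int, int] = (4, 7)
    exudate_intensity: float = 0.95
    hemorrhage_intensity: float = 0.05
    exudate_radius: tuple[float, float] = (3.0, 4.5)
    hemorrhage_radius: tuple[float, float] = (1.0, 1.8)
    dr_fraction: float = 0.25
    seed: int = 0
    rgb: bool = False

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ConfigurationError("size must be >= 16")
        if not 0.0 < self.dr_fraction < 1.0:
            raise ConfigurationError("dr_fraction must lie in (0, 1)")
        if not 0.0 <= self.hemorrhage_intensity <= 1.0 or not 0.0 <= self.exudate_intensity <= 1.0:
            raise ConfigurationError("lesion intensities must lie in [0, 1]")
        if self.lesion_count_range[0] < 2:
            raise ConfigurationError("DR images need at least one exudate and one hemorrhage")


# background intensity levels; exudates must be strictly brighter than all of
# these for the class signal to be separable
_BG = 0.05
_DISC_CENTER = 0.55
_DISC_RIM = 0.30
_VESSEL = 0.20


def _disc_mask(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    radius = 0.45 * size
    return r <= radius, r / radius


def _paint_disc(size: int) -> np.ndarray:
    mask, rel_r = _disc_mask(size)
    img = np.full((size, size), _BG)
    gradient = _DISC_CENTER - (_DISC_CENTER - _DISC_RIM) * np.clip(rel_r, 0.0, 1.0)
    img[mask] = gradient[mask]
    return img


def _walk_vessel(img: np.ndarray, rng: np.random.Generator) -> None:
    size = img.shape[0]
    c = (size - 1) / 2.0
    radius = 0.45 * size
    angle = rng.uniform(0.0, 2.0 * np.pi)
    y, x = c, c
    while np.hypot(y - c, x - c) < radius - 1:
        angle += rng.normal(0.0, 0.35)
        y += np.sin(angle)
        x += np.cos(angle)
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < size and 0 <= ix < size:
            img[iy, ix] = _VESSEL


def _paint_spot(img: np.ndarray, cy: float, cx: float, radius: float, value: float) -> None:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    img[np.hypot(yy - cy, xx - cx) <= radius] = value

def _lesion_center(size: int, rng: np.random.Generator) -> tuple[float, float]:
    c = (size - 1) / 2.0
    rho = rng.uniform(0.0, 0.30 * size)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return c + rho * np.sin(phi), c + rho * np.cos(phi)


def generate_fundus_image(label: int, params: FundusParams, rng: np.random.Generator) -> np.ndarray:
    """One seed-reproducible image; label 1 adds exudate blobs + hemorrhage dots."""
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    img = _paint_disc(params.size)
    for _ in range(params.vessel_count):
        _walk_vessel(img, rng)
    if label == 1:
        lo, hi = params.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1))
        # bright exudates dominate so the class raises total image brightness
        # by a clear margin (keeps the pipeline's learning task well-posed)
        n_hemorrhages = max(1, n_lesions // 3)
        n_exudates = max(1, n_lesions - n_hemorrhages)
        scale = params.size / 64.0
        for _ in range(n_exudates):
            cy, cx = _lesion_center(params.size, rng)
            radius = rng.uniform(*params.exudate_radius) * scale
            _paint_spot(img, cy, cx, radius, params.exudate_intensity)
        for _ in range(n_hemorrhages):
            cy, cx = _lesion_center(params.size, rng)
            radius = rng.uniform(*params.hemorrhage_radius) * scale
            _paint_spot(img, cy, cx, radius, params.hemorrhage_intensity)
    img = np.clip(img, 0.0, 1.0)
    if params.rgb:
        # fundus convention: lesions and vessels live mostly in the green channel
        return np.stack([0.8 * img, img, 0.5 * img], axis=-1)
    return img


def generate_dataset(
    n: int,
    params: FundusParams,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate ``n`` labeled images; optionally write PNGs + a CSV manifest.

    Returns (images, labels, manifest).  ``round(n * dr_fraction)`` images
    are DR-positive; positives come first in neither order — labels are
    shuffled so folds are non-trivial.
    """
    if n < 10:
        raise ConfigurationError("n must be >= 10")
    n_dr = int(round(n * params.dr_fraction))
    if n_dr < 1 or n - n_dr < 1:
        raise ConfigurationError("dr_fraction leaves one class empty")
    labels = np.concatenate([np.ones(n_dr, dtype=int), np.zeros(n - n_dr, dtype=int)])
    labels = rng.permutation(labels)
    images = np.array([generate_fundus_image(int(lbl), params, rng) for lbl in labels])

    filenames = [f"fundus_{i:05d}.png" for i in range(n)]
    manifest = pd.DataFrame(
        {"filename": filenames, "label": labels, "synthetic": False, "size": params.size}
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, img in zip(filenames, images):
            save_png(img, out_dir / fname)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, labels, manifest


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as an 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    data = np.round(arr * 255.0).astype(np.uint8)
    mode = "RGB" if data.ndim == 3 else "L"
    Image.fromarray(data, mode=mode).save(path)


def load_png(path: str | Path) -> np.ndarray:
    """Read a PNG back into a [0, 1] float array."""
    with Image.open(path) as im:
        return np.asarray(im, dtype=float) / 255.0


def load_image_set(manifest_path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load images referenced by a manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    images = np.array([load_png(manifest_path.parent / f) for f in manifest["filename"]])
    return images, manifest["label"].to_numpy(dtype=int), manifest
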