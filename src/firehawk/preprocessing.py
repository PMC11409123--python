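"""Image preprocessing: normalization, impulse noise, fuzzy denoising, PSNR.

Images are plain 2-D (or HxWxC) float arrays with intensities in [0, 1]
after :func:`minmax_normalize`.  The denoiser is a fuzzy-rule impulse
filter: pixel intensities are fuzzified into pepper-extreme / signal /
salt-extreme triangular sets; a pixel is flagged as noise when an extreme
membership dominates its signal membership AND it deviates from the local
neighbor median by more than a threshold; flagged pixels are restored from
signal-weighted non-flagged neighborhood evidence.  Non-flagged pixels are
never modified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class DimensionError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WMParams:
    """Tuning knobs of the fuzzy impulse denoiser."""

    window: int = 3
    t_low: float = 0.02
    t_high: float = 0.98
    delta: float = 0.4
    max_iters: int = 3

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("window must be an odd integer >= 3")
        if not 0.0 <= self.t_low < self.t_high <= 1.0:
            raise ConfigurationError("need 0 <= t_low < t_high <= 1")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Affine map of intensities onto [0, 1]; a constant image maps to zeros."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise DimensionError("empty image")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def add_salt_pepper(image: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt each pixel independently with probability ``density``.

    Corrupted pixels become 0 (pepper) or 1 (salt) with equal probability.
    """
    if not 0.0 <= density <= 1.0:
        raise ConfigurationError("density must lie in [0, 1]")
    image = np.asarray(image, dtype=float)
    corrupted = rng.random(image.shape) < density
    salt = rng.random(image.shape) < 0.5
    out = image.copy()
    out[corrupted & salt] = 1.0
    out[corrupted & ~salt] = 0.0
    return out


def _memberships(image: np.ndarray, params: WMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triangular memberships of each pixel to pepper / signal / salt sets."""
    pepper = np.clip(1.0 - image / max(params.t_low, 1e-12), 0.0, 1.0)
    salt = np.clip((image - params.t_high) / max(1.0 - params.t_high, 1e-12), 0.0, 1.0)
    signal = 1.0 - np.maximum(pepper, salt)
    return pepper, signal, salt


def _neighbor_windows(image: np.ndarray, window: int) -> np.ndarray:
    """(H, W, window*window) view of reflect-padded neighborhoods."""
    pad = window // 2
    padded = np.pad(image, pad, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    return view.reshape(image.shape[0], image.shape[1], window * window)


def _neighbor_median(image: np.ndarray, window: int) -> np.ndarray:
    """Median over the window excluding the center pixel."""
    wins = _neighbor_windows(image, window)
    center = window * window // 2
    neighbors = np.delete(wins, center, axis=2)
    return np.median(neighbors, axis=2)


def wm_denoise(image: np.ndarray, params: WMParams | None = None) -> np.ndarray:
    """Fuzzy-rule impulse denoiser for normalized images.

    Multichannel images are processed channel by channel.  Pixels never
    flagged as noise pass through bit-identically; once a pixel is deemed
    clean it stays clean, so the flag count is non-increasing across
    iterations.
    """
    params = params or WMParams()
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return np.stack([wm_denoise(image[..., c], params) for c in range(image.shape[-1])], axis=-1)
    if image.ndim != 2:
        raise DimensionError("expected a 2-D image or an HxWxC stack")
    if min(image.shape) < params.window:
        raise DimensionError("image smaller than the filter window")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ConfigurationError("denoiser expects intensities in [0, 1]; normalize first")

    out = image.copy()
    eligible = np.ones(out.shape, dtype=bool)  # pixels still allowed to be flagged
    for _ in range(params.max_iters):
        pepper, signal, salt = _memberships(out, params)
        extreme = np.maximum(pepper, salt)
        med = _neighbor_median(out, params.window)
        flags = eligible & (extreme > signal) & (np.abs(out - med) > params.delta)
        if not flags.any():
            break
        out = _restore(out, flags, signal, params)
        eligible = flags  # only just-restored pixels may be re-flagged
    return np.clip(out, 0.0, 1.0)


def _restore(image: np.ndarray, flags: np.ndarray, signal: np.ndarray, params: WMParams) -> np.ndarray:
    """Replace flagged pixels from non-flagged neighborhood evidence.

    Preference order per flagged pixel: signal-membership-weighted mean of
    non-flagged window neighbors, then their plain median, then a 5x5
    window expansion, finally the global median of non-flagged pixels.
    """
    out = image.copy()
    clean = ~flags
    global_fallback = float(np.median(image[clean])) if clean.any() else float(np.median(image))

    wins = _neighbor_windows(image, params.window)
    w_signal = _neighbor_windows(np.where(clean, signal, 0.0), params.window)
    w_clean = _neighbor_windows(clean.astype(float), params.window)
    center = params.window * params.window // 2

    big = params.window + 2
    wins5 = _neighbor_windows(image, big)
    w_clean5 = _neighbor_windows(clean.astype(float), big)
    center5 = big * big // 2

    ys, xs = np.nonzero(flags)
    for y, x in zip(ys, xs):
        vals = np.delete(wins[y, x], center)
        weights = np.delete(w_signal[y, x], center)
        cmask = np.delete(w_clean[y, x], center).astype(bool)
        if weights.sum() > 0:
            out[y, x] = float(np.sum(vals * weights) / weights.sum())
        elif cmask.any():
            out[y, x] = float(np.median(vals[cmask]))
        else:
            vals5 = np.delete(wins5[y, x], center5)
            cmask5 = np.delete(w_clean5[y, x], center5).astype(bool)
            if cmask5.any():
                out[y, x] = float(np.median(vals5[cmask5]))
            else:
                out[y, x] = global_fallback
    return out


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for [0, 1] images; +inf if identical."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise DimensionError("shape mismatch")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)
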