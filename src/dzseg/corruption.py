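"""Image corruption operators for robustness evaluation.

Five operators at severities 1-5, parameterized after the common-corruptions
benchmark: additive Gaussian noise, motion blur (directional line kernel),
smoke (the benchmark's fog-style plasma-fractal haze), contrast reduction and
brightness increase.  All operators preserve shape and dtype, clip to
[0, 255], and are deterministic given (image, spec) — the stochastic ones
(noise, motion-blur direction, smoke fractal) draw from the spec's seed.

Corruption simulates degraded acquisition: it is applied to the clean
native-resolution frame *before* prompt overlay and resizing, so user-drawn
prompts stay crisp.  Label masks are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve

from .synthetic import ImageSample

__all__ = ["CorruptionSpec", "CORRUPTION_TYPES", "corrupt", "corrupt_dataset",
           "adjust_contrast", "adjust_brightness", "psnr"]

CORRUPTION_TYPES = ("gaussian_noise", "motion_blur", "smoke", "contrast", "brightness")

# severity tables (index = severity - 1), following the common-corruptions
# benchmark's parameterization on [0, 1]-scaled images
_GAUSS_SIGMA = (0.08, 0.12, 0.18, 0.26, 0.38)
_MOTION = ((10, 3), (15, 5), (15, 8), (15, 12), (20, 15))   # (radius, sigma)
_SMOKE = ((1.5, 2.0), (2.0, 2.0), (2.5, 1.7), (2.5, 1.5), (3.0, 1.4))  # (intensity, wibble decay)
_CONTRAST = (0.4, 0.3, 0.2, 0.1, 0.05)
_BRIGHTNESS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class CorruptionSpec:
    """One corruption operator at one severity; seed feeds stochastic types."""

    type: str
    severity: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.type not in CORRUPTION_TYPES:
            raise ValueError(
                f"unknown corruption type {self.type!r}; expected one of {CORRUPTION_TYPES}")
        if self.severity not in (1, 2, 3, 4, 5):
            raise ValueError(f"severity must be in 1..5, got {self.severity}")


def _to_float(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float64) / 255.0

def _to_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8)


def adjust_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale contrast about the image's mean luminance; factor 1 is identity."""
    if factor == 1.0:
        return np.array(image, dtype=np.uint8, copy=True)
    x = _to_float(image)
    mean = x.mean(axis=(0, 1), keepdims=True)
    return _to_uint8((x - mean) * factor + mean)


def adjust_brightness(image: np.ndarray, delta: float) -> np.ndarray:
    """Add ``delta`` (on the [0, 1] scale) to the HSV value channel."""
    from skimage.color import hsv2rgb, rgb2hsv
    hsv = rgb2hsv(_to_float(image))
    hsv[..., 2] = np.clip(hsv[..., 2] + delta, 0.0, 1.0)
    return _to_uint8(hsv2rgb(hsv))


def _gaussian_noise(image: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    x = _to_float(image)
    return _to_uint8(x + rng.standard_normal(x.shape) * sigma)


def _motion_kernel(radius: int, sigma: float, angle: float) -> np.ndarray:
    """Gaussian-weighted line kernel of length 2*radius+1 at ``angle``."""
    n = 2 * radius + 1
    k = np.zeros((n, n))
    t = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-t * t / (2.0 * sigma * sigma))
    rows = np.clip(np.rint(radius + t * np.sin(angle)).astype(int), 0, n - 1)
    cols = np.clip(np.rint(radius + t * np.cos(angle)).astype(int), 0, n - 1)
    np.add.at(k, (rows, cols), w)
    return k / k.sum()


def _motion_blur(image: np.ndarray, radius: int, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    angle = rng.uniform(-np.pi / 4, np.pi / 4)
    k = _motion_kernel(radius, sigma, angle)
    x = _to_float(image)
    out = np.stack([convolve(x[..., c], k, mode="nearest") for c in range(x.shape[2])],
                   axis=-1)
    return _to_uint8(out)


def _plasma_fractal(size: int, wibble_decay: float, rng: np.random.Generator) -> np.ndarray:
    """Cloud-like heightmap in [0, 1]: periodic diamond-square, size = 2**k.

    Noise amplitude shrinks by ``wibble_decay`` per subdivision level, which
    controls how smooth (fog-like) versus grainy the haze is.
    """
    assert size >= 2 and size & (size - 1) == 0, "fractal size must be a power of two"
    grid = np.zeros((size, size), dtype=np.float64)
    step, amp = size, 100.0
    while step >= 2:
        half = step // 2
        c = grid[::step, ::step]
        # diamond: cell centers from the four surrounding corners (wrapping)
        center = (c + np.roll(c, -1, 0) + np.roll(c, -1, 1)
                  + np.roll(np.roll(c, -1, 0), -1, 1)) / 4.0
        grid[half::step, half::step] = center + rng.uniform(-amp, amp, center.shape)
        d = grid[half::step, half::step]
        # square: edge midpoints from two corners and two fresh centers
        v = (c + np.roll(c, -1, 0) + d + np.roll(d, 1, 1)) / 4.0
        grid[half::step, ::step] = v + rng.uniform(-amp, amp, v.shape)
        h = (c + np.roll(c, -1, 1) + d + np.roll(d, 1, 0)) / 4.0
        grid[::step, half::step] = h + rng.uniform(-amp, amp, h.shape)
        step = half
        amp /= wibble_decay
    grid -= grid.min()
    return grid / max(grid.max(), 1e-12)


def _smoke(image: np.ndarray, intensity: float, wibble_decay: float,
           rng: np.random.Generator) -> np.ndarray:
    x = _to_float(image)
    h, w = x.shape[:2]
    size = 1 << int(np.ceil(np.log2(max(h, w, 2))))
    haze = _plasma_fractal(size, wibble_decay, rng)[:h, :w]
    max_val = x.max()
    out = x + intensity * haze[..., None]
    return _to_uint8(out * max_val / max(out.max(), 1e-9))


def corrupt(image: np.ndarray, spec: CorruptionSpec) -> np.ndarray:
    """Apply one corruption operator; output shape/dtype match the input."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.severity - 1
    if spec.type == "gaussian_noise":
        return _gaussian_noise(image, _GAUSS_SIGMA[s], rng)
    if spec.type == "motion_blur":
        return _motion_blur(image, *_MOTION[s], rng)
    if spec.type == "smoke":
        return _smoke(image, *_SMOKE[s], rng)
    if spec.type == "contrast":
        return adjust_contrast(image, _CONTRAST[s])
    return adjust_brightness(image, _BRIGHTNESS[s])


def corrupt_dataset(samples: list[ImageSample], spec: CorruptionSpec) -> list[ImageSample]:
    """Corrupt every image; per-sample seeds derive from the spec's seed.

    Masks pass through untouched — corruption degrades acquisition, not
    annotation.
    """
    if not samples:
        raise ValueError("sample list is empty")
    out = []
    for i, sample in enumerate(samples):
        child = int(np.random.SeedSequence(spec.seed, spawn_key=(i,)).generate_state(1)[0])
        corrupted = corrupt(sample.image, replace(spec, seed=child))
        out.append(ImageSample(image=corrupted, mask=sample.mask.copy(),
                               id=f"{sample.id}_c{spec.type}{spec.severity}"))
    return out


def psnr(clean: np.ndarray, corrupted: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB between two 8-bit images."""
    mse = np.mean((np.asarray(clean, float) - np.asarray(corrupted, float)) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / mse))
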