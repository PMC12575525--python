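"""Seeded synthetic endoscopic-like scenes with ambiguous zone boundaries.

Real dissection-zone frames show a safe-to-cut region whose texture is only
subtly different from the surrounding tissue, with a blurred, irregular
boundary.  This module emulates exactly those properties at desk scale: a
single star-convex "dissection zone" blob, rendered in reddish tissue-like
hues, whose luminance offset against the background is controlled by
``texture_contrast`` and whose edge is softened by a Gaussian of radius
``boundary_softness``.  At full contrast with a hard edge the mask is
recoverable from the image by luminance thresholding; as contrast drops the
two zones become progressively indistinguishable, which is the learnability
dial the training experiments rely on.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError

__all__ = ["SceneSpec", "ImageSample", "generate_scene", "generate_dataset"]

# tissue palette: background base colour and the per-channel luminance offset
# of the dissection zone at texture_contrast == 1
_BG_BASE = np.array([140.0, 70.0, 65.0])
_FG_OFFSET = np.array([90.0, 95.0, 95.0])
_NOISE_STD = 8.0         # smooth texture noise, std in 8-bit luminance units
_NOISE_CLIP = 24.0       # hard clip keeps full-contrast scenes separable
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    image_size: int = 64
    boundary_softness: float = 2.0
    texture_contrast: float = 0.10
    blob_complexity: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.image_size, (int, np.integer)) and self.image_size >= 32):
            raise ConfigError(f"image_size must be an integer >= 32, got {self.image_size}")
        if self.boundary_softness < 0:
            raise ConfigError(f"boundary_softness must be >= 0, got {self.boundary_softness}")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ConfigError(f"texture_contrast must be in [0, 1], got {self.texture_contrast}")
        if self.blob_complexity < 0:
            raise ConfigError(f"blob_complexity must be >= 0, got {self.blob_complexity}")


@dataclass
class ImageSample:
    """An RGB frame with its per-pixel zone labels (0 = no-go, 1 = dissection)."""

    image: np.ndarray
    mask: np.ndarray
    id: str = ""

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ConfigError(f"image must be HxWx3, got shape {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ConfigError(
                f"mask shape {self.mask.shape} does not match image {self.image.shape[:2]}")
        labels = np.unique(self.mask)
        if not np.isin(labels, [0, 1]).all():
            raise ConfigError(f"mask labels must be in {{0, 1}}, found {labels.tolist()}")


def _star_blob(size: int, complexity: int, rng: np.random.Generator) -> np.ndarray:
    """Rasterize a star-convex blob covering 5-40% of a size x size grid."""
    target_frac = rng.uniform(0.08, 0.32)
    center = size / 2.0 + rng.uniform(-0.1, 0.1, size=2) * size
    # radial harmonic series r(theta) = r0 * (1 + sum_k a_k cos + b_k sin)
    ks = np.arange(2, complexity + 2)
    a = rng.uniform(-1.0, 1.0, size=len(ks)) * 0.35 / np.maximum(ks - 1, 1)
    b = rng.uniform(-1.0, 1.0, size=len(ks)) * 0.35 / np.maximum(ks - 1, 1)
    # keep the profile strictly positive (star-convexity about the center)
    wiggle = np.abs(a).sum() + np.abs(b).sum()
    if wiggle > 0.55:
        a *= 0.55 / wiggle
        b *= 0.55 / wiggle
    # continuum area of the star polygon: pi * r0^2 * (1 + sum(amp^2)/2)
    amp2 = (a * a + b * b).sum()
    r0 = size * np.sqrt(target_frac / (np.pi * (1.0 + amp2 / 2.0)))

    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rr - center[0], cc - center[1]
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    profile = np.ones_like(theta)
    for k, ak, bk in zip(ks, a, b):
        profile += ak * np.cos(k * theta) + bk * np.sin(k * theta)
    for _ in range(8):
        mask = dist < r0 * profile
        frac = mask.mean()
        if 0.05 <= frac <= 0.40:
            break
        # rescale toward the target; clipping at image borders motivates iterating
        r0 *= np.sqrt(np.clip(target_frac / max(frac, 1e-6), 0.5, 2.0))
    else:
        # degenerate harmonics: fall back to a centered disk of the target area
        mask = dist < size * np.sqrt(target_frac / np.pi)
    return mask


def generate_scene(spec: SceneSpec) -> ImageSample:
    """Render one scene; deterministic in ``spec`` (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    mask = _star_blob(size, spec.blob_complexity, rng)

    # smooth texture noise shared by both zones; the zones differ only by a
    # contrast-scaled offset applied through the (optionally blurred) alpha
    noise = rng.standard_normal((size, size))
    noise = gaussian_filter(noise, sigma=2.0, mode="reflect")
    noise *= _NOISE_STD / max(noise.std(), 1e-9)
    noise = np.clip(noise, -_NOISE_CLIP, _NOISE_CLIP)

    if spec.boundary_softness > 0:
        alpha = gaussian_filter(mask.astype(float), sigma=spec.boundary_softness,
                                mode="constant")
    else:
        alpha = mask.astype(float)

    channel_weight = np.array([1.0, 0.85, 0.85])
    image = (_BG_BASE[None, None, :]
             + noise[:, :, None] * channel_weight[None, None, :]
             + alpha[:, :, None] * (spec.texture_contrast * _FG_OFFSET)[None, None, :])
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    sample = ImageSample(image=image, mask=mask.astype(np.uint8),
                         id=f"scene_{spec.seed}")
    sample.validate()
    return sample


def _child_seed(master_seed: int, index: int) -> int:
    # counter-based derivation: child i is independent of the total count
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0])


def generate_dataset(spec_template: SceneSpec, count: int, seed: int) -> list[ImageSample]:
    """Generate ``count`` mutually distinct scenes from one master seed."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    spec_template.validate()
    samples = []
    for i in range(count):
        spec = replace(spec_template, seed=_child_seed(seed, i))
        sample = generate_scene(spec)
        sample.id = f"scene_{i:04d}"
        samples.append(sample)
    return samples
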