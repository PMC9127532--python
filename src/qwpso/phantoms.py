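"""Seeded generator of synthetic tumor-like phantom images.

The phantoms emulate the qualitative structure of the tumor silhouettes
the segmenters target: a bright object on a darker background, where the
object is a plain disc, two lobes joined by a narrow hyperbolic-profile
neck ("bottleneck"), or a disc with long tapering extensions ("dualtail").
Additive Gaussian noise models acquisition noise; the ground-truth mask is
always the exact noiseless silhouette.

A ``neck_gap > 0`` carves a horizontal band out of the bottleneck's neck,
splitting the object into two disjoint lobes — the configuration in which
long-range (wormhole) cluster linking is required to recover the object
as one region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ParameterError


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one phantom image.

    noise_sd is the standard deviation of the zero-mean Gaussian intensity
    noise (8-bit units); neck_width applies to bottlenecks, tail_length and
    tail_taper to dualtails, neck_gap carves the gap-separated bottleneck
    variant.
    """

    shape: str = "disc"
    size: int = 64
    object_gray: int = 200
    background_gray: int = 50
    noise_sd: float = 0.0
    neck_width: int = 3
    neck_gap: int = 0
    tail_length: int = 15
    tail_taper: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "bottleneck", "dualtail"):
            raise ParameterError(f"unknown phantom shape {self.shape!r}")
        if self.size < 16:
            raise ParameterError(f"size must be >= 16, got {self.size}")
        if not (0 <= self.background_gray < self.object_gray <= 255):
            raise ParameterError(
                "need 0 <= background_gray < object_gray <= 255, got "
                f"{self.background_gray}, {self.object_gray}"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.shape == "bottleneck" and self.neck_width < 1:
            raise ParameterError(f"neck_width must be >= 1, got {self.neck_width}")
        if self.neck_gap < 0:
            raise ParameterError(f"neck_gap must be >= 0, got {self.neck_gap}")
        if self.shape == "dualtail" and self.tail_length < 1:
            raise ParameterError(f"tail_length must be >= 1, got {self.tail_length}")
        if not (0 <= self.tail_taper <= 1):
            raise ParameterError(f"tail_taper must be in [0, 1], got {self.tail_taper}")


def _span(center: int, width: int) -> tuple[int, int]:
    """Integer column span of `width` pixels around `center` (inclusive)."""
    lo = center - (width - 1) // 2
    hi = center + width // 2
    return lo, hi


def _disc_mask(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    rad = size / 4.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= rad**2


def _bottleneck_mask(size: int, neck_width: int, neck_gap: int) -> np.ndarray:
    """Two lobes joined by a neck whose width grows quadratically away
    from the central row — a rasterizable stand-in for the hyperbolic
    half-width profile of a wormhole throat."""
    mask = np.zeros((size, size), dtype=bool)
    cy = cx = size // 2
    lobe_r = size / 6.0
    lobe_off = int(round(size / 4.0))
    yy, xx = np.mgrid[0:size, 0:size]
    for sgn in (-1, 1):
        mask |= (yy - (cy + sgn * lobe_off)) ** 2 + (xx - cx) ** 2 <= lobe_r**2
    # neck: width(y) = neck_width + 2*floor(k*y^2), capped at the lobe width
    k = (lobe_r - neck_width / 2.0) / max(lobe_off**2, 1)
    for y in range(cy - lobe_off, cy + lobe_off + 1):
        dy = y - cy
        width = neck_width + 2 * int(np.floor(k * dy * dy))
        width = min(width, int(2 * lobe_r))
        lo, hi = _span(cx, width)
        mask[y, max(lo, 0) : min(hi, size - 1) + 1] = True
    if neck_gap > 0:
        glo, ghi = _span(cy, neck_gap)
        mask[glo : ghi + 1, :] = False
    return mask


def _dualtail_mask(size: int, tail_length: int, tail_taper: float) -> np.ndarray:
    """A central disc with two horizontal tails whose half-width tapers
    linearly with distance from the disc rim (never below half a pixel,
    so the tail tips stay one pixel wide)."""
    mask = np.zeros((size, size), dtype=bool)
    cy = cx = size // 2
    rad = size / 5.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    h0 = max(rad * 0.4, 1.0)
    rim = int(np.floor(rad))
    for t in range(0, tail_length + 1):
        half = max(0.5, h0 * (1.0 - tail_taper * t / tail_length))
        for sgn in (-1, 1):
            x = cx + sgn * (rim + t)
            if 0 <= x < size:
                hw = int(np.floor(half))
                mask[cy - hw : cy + hw + 1, x] = True
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build (image, truth mask) for a phantom spec.

    The image is object_gray on the mask and background_gray elsewhere,
    plus zero-mean Gaussian noise of sd ``noise_sd``, rounded and clipped
    to [0, 255]. Deterministic given ``spec.seed``; the mask does not
    depend on the noise.
    """
    if spec.shape == "disc":
        mask = _disc_mask(spec.size)
    elif spec.shape == "bottleneck":
        mask = _bottleneck_mask(spec.size, spec.neck_width, spec.neck_gap)
    else:
        mask = _dualtail_mask(spec.size, spec.tail_length, spec.tail_taper)
    img = np.where(mask, float(spec.object_gray), float(spec.background_gray))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, mask


def phantom_suite(seed: int = 0) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """The fixed phantom battery: disc, bottlenecks (neck widths 2 and 5),
    dualtails (tail lengths 10 and 20), each at noise sd 0 and 10, 64x64.

    Returns ten (image, mask, name) triples; names encode shape and noise.
    """
    shapes = [
        PhantomSpec(shape="disc", size=64),
        PhantomSpec(shape="bottleneck", size=64, neck_width=2),
        PhantomSpec(shape="bottleneck", size=64, neck_width=5),
        PhantomSpec(shape="dualtail", size=64, tail_length=10),
        PhantomSpec(shape="dualtail", size=64, tail_length=20),
    ]
    names = ["disc", "bottleneck_w2", "bottleneck_w5", "dualtail_l10", "dualtail_l20"]
    out = []
    for idx, (spec, name) in enumerate(zip(shapes, names)):
        for sd in (0.0, 10.0):
            s = PhantomSpec(
                shape=spec.shape,
                size=spec.size,
                neck_width=spec.neck_width,
                tail_length=spec.tail_length,
                tail_taper=spec.tail_taper,
                noise_sd=sd,
                seed=(seed + 101 * idx + int(sd)) % (2**31),
            )
            img, mask = make_phantom(s)
            out.append((img, mask, f"{name}_sd{int(sd)}"))
    return out
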