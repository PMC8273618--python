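"""Synthetic osteochondral phantoms with analytically known thickness.

A phantom emulates the three-phase appearance of an osteochondral image:
dark articular cartilage on top, an intermediate-intensity calcified
cartilage (CC) band of prescribed, spatially varying thickness, and bright
trabecular bone with speckle texture below. Small dark chondrocyte-like
voids are placed fully inside the CC band, and additive Gaussian noise is
applied last. The ground-truth mask and the continuous thickness field are
returned alongside the image, so segmentation and morphometry can be
validated against a known answer.

Depth runs along axis 0 (rows in 2D, slices in 3D); the thickness field is
indexed by the remaining lateral coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, GridMetadata, Image2D, ImageVolume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, and noise parameters of a synthetic sample.

    The CC band thickness at lateral position x (2D) is
    ``base + amplitude * sin(2*pi*x/period) + roughness-noise``; in 3D the
    sinusoid is separable in the two lateral coordinates. Intensity means
    must be strictly ordered cartilage < cc < bone so the phases are
    separable at zero noise.
    """

    shape: tuple[int, ...] = (128, 192)
    base_thickness_px: float = 24.0
    amplitude_px: float = 5.0
    spatial_period_px: float = 96.0
    interface_roughness_px: float = 0.0
    cartilage_depth_frac: float = 0.35
    intensity_means: tuple[float, float, float] = (0.25, 0.55, 0.85)
    noise_sd: float = 0.03
    void_density_per_1000px: float = 0.5
    void_radius_px_range: tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2D or 3D")
        if self.base_thickness_px - self.amplitude_px < 2:
            raise ValueError("base_thickness_px - amplitude_px must be >= 2 (band never vanishes)")
        c, cc, b = self.intensity_means
        if not (0 <= c < cc < b <= 1):
            raise ValueError("intensity_means must satisfy 0 <= cartilage < cc < bone <= 1")
        if self.amplitude_px < 0 or self.interface_roughness_px < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, roughness, and noise_sd must be non-negative")
        if self.spatial_period_px <= 0:
            raise ValueError("spatial_period_px must be positive")
        lo, hi = self.void_radius_px_range
        if not (0 < lo <= hi):
            raise ValueError("void_radius_px_range must be ordered and positive")


@dataclass
class PhantomSample:
    """A generated phantom: image, ground-truth CC mask, and thickness field."""

    image: Image2D | ImageVolume
    truth_mask: BinaryMask
    thickness_field_px: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, ...], sigma: float) -> np.ndarray:
    """Zero-mean unit-amplitude-ish smooth noise (Gaussian-filtered white noise)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="wrap")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _thickness_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    lateral = spec.shape[1:] if len(spec.shape) == 3 else spec.shape[1:]
    w = 2.0 * np.pi / spec.spatial_period_px
    if len(spec.shape) == 2:
        x = np.arange(spec.shape[1])
        t = spec.base_thickness_px + spec.amplitude_px * np.sin(w * x)
    else:
        r = np.arange(spec.shape[1])[:, None]
        c = np.arange(spec.shape[2])[None, :]
        t = spec.base_thickness_px + spec.amplitude_px * np.sin(w * r) * np.sin(w * c)
    if spec.interface_roughness_px > 0:
        t = t + spec.interface_roughness_px * _smooth_noise(rng, lateral, sigma=4.0)
    # clamp so the band never vanishes after roughness
    return np.maximum(t, 2.0)


def _place_voids(
    rng: np.random.Generator,
    band_top: np.ndarray,
    heights: np.ndarray,
    spec: PhantomSpec,
    ndim: int,
) -> list[tuple[tuple[int, ...], float]]:
    """Sample dark void centres/radii strictly inside the CC band."""
    n_band = int(heights.sum())
    n_voids = rng.poisson(spec.void_density_per_1000px * n_band / 1000.0)
    lo, hi = spec.void_radius_px_range
    voids: list[tuple[tuple[int, ...], float]] = []
    lateral_shape = band_top.shape
    for _ in range(n_voids):
        for _attempt in range(20):
            pos = tuple(int(rng.integers(0, s)) for s in lateral_shape)
            r = float(rng.uniform(lo, hi))
            top, h = float(band_top[pos]), float(heights[pos])
            if h < 2 * r + 2:
                continue
            depth = float(rng.uniform(top + r + 1, top + h - r - 1))
            voids.append(((depth,) + tuple(float(p) for p in pos), r))
            break
    return voids


def _render(spec: PhantomSpec, rng: np.random.Generator):
    ndim = len(spec.shape)
    depth = spec.shape[0]
    tfield = _thickness_field(spec, rng)
    heights = np.round(tfield).astype(int)
    top_row = int(round(spec.cartilage_depth_frac * depth))
    band_top = np.full(tfield.shape, top_row, dtype=int)

    z = np.arange(depth).reshape((-1,) + (1,) * (ndim - 1))
    in_band = (z >= band_top[None]) & (z < (band_top + heights)[None])
    in_bone = z >= (band_top + heights)[None]

    cart, cc, bone = spec.intensity_means
    img = np.full(spec.shape, cart, dtype=np.float64)
    img[in_band] = cc
    # trabecular speckle: multiplicative smoothed binary noise on the bone phase,
    # softening the CC/bone boundary into a gradient rather than a step
    speckle = np.clip(_smooth_noise(rng, spec.shape, sigma=2.0), -1.0, 1.0)
    bone_tex = bone * (1.0 + 0.15 * speckle)
    img[in_bone] = bone_tex[in_bone]

    # chondrocyte-like voids: dark discs/balls fully inside the band; the truth
    # mask keeps them as CC (annotation convention: small cavities included)
    for centre, r in _place_voids(rng, band_top, heights, spec, ndim):
        grids = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        img[d2 <= r * r] = cart

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(img, 0.0, 1.0)
    return img, in_band.astype(np.uint8), tfield


def generate_phantom_2d(spec: PhantomSpec, meta: GridMetadata | None = None) -> PhantomSample:
    """Generate a 2D histology-like phantom. Deterministic in (spec, spec.seed)."""
    if len(spec.shape) != 2:
        raise ValueError("generate_phantom_2d requires a 2D shape")
    rng = np.random.default_rng(spec.seed)
    img, mask, tfield = _render(spec, rng)
    meta = meta or GridMetadata(modality_tag="histology")
    return PhantomSample(Image2D(img, meta), BinaryMask(mask, meta), tfield, spec)


def generate_phantom_3d(spec: PhantomSpec, meta: GridMetadata | None = None) -> PhantomSample:
    """Generate a 3D µCT-like phantom volume. Deterministic in (spec, spec.seed)."""
    if len(spec.shape) != 3:
        raise ValueError("generate_phantom_3d requires a 3D shape")
    rng = np.random.default_rng(spec.seed)
    img, mask, tfield = _render(spec, rng)
    meta = meta or GridMetadata(modality_tag="microct")
    return PhantomSample(ImageVolume(img, meta), BinaryMask(mask, meta), tfield, spec)


def generate_phantom(spec: PhantomSpec, meta: GridMetadata | None = None) -> PhantomSample:
    if len(spec.shape) == 2:
        return generate_phantom_2d(spec, meta)
    return generate_phantom_3d(spec, meta)


def prescribed_mean_thickness_um(sample: PhantomSample, meta: GridMetadata) -> float:
    """Mean of the analytic thickness field, converted to micrometres."""
    tfield = np.asarray(sample.thickness_field_px)
    if tfield.size == 0:
        raise ValueError("phantom sample has an empty thickness field")
    return float(tfield.mean() * meta.pixel_size_um)
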