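"""Binary-mask cleanup between thresholding and morphometry.

Three operations, applied in modality-specific order:

* histology (2D): remove connected components smaller than 500 pixels
  (folds in a section can legitimately disconnect large CC pieces, which
  are kept), then median filter with a 12-pixel radius;
* micro-CT (3D): keep only the largest connected component (a sweep that
  discards false positives far from the CC layer), then 3D median filter
  with a 12-pixel radius.

The median filter is an exact majority vote over a Euclidean disc/ball
footprint with reflective boundaries; an exact 50/50 tie resolves to
foreground so thin structures are not eroded by ties.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import BinaryMask

DEFAULT_MIN_REGION_PX = 500
DEFAULT_MEDIAN_RADIUS_PX = 12


def _structure(ndim: int, connectivity: int | None = None) -> np.ndarray:
    # maximal connectivity by default: 8-neighbourhood in 2D, 26 in 3D,
    # so thin diagonal CC bridges are not split into separate components
    conn = connectivity if connectivity is not None else ndim
    return ndimage.generate_binary_structure(ndim, conn)


def remove_small_regions(
    mask: BinaryMask,
    min_size: int = DEFAULT_MIN_REGION_PX,
    connectivity: int | None = None,
) -> BinaryMask:
    """Remove connected components with strictly fewer than ``min_size`` pixels.

    Components of exactly ``min_size`` pixels survive. Idempotent; output
    foreground is a subset of input foreground.
    """
    arr = mask.values
    labels, n = ndimage.label(arr, structure=_structure(arr.ndim, connectivity))
    if n == 0:
        return BinaryMask(arr.copy(), mask.meta)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes >= min_size
    return BinaryMask(keep[labels] & arr, mask.meta)


def keep_largest_component(
    mask: BinaryMask, connectivity: int | None = None
) -> BinaryMask:
    """Keep only the largest connected component.

    Size ties resolve to the component whose first element comes earliest
    in raster (slice, row, column) order, which is deterministic across
    runs. An empty mask passes through with a warning.
    """
    arr = mask.values
    labels, n = ndimage.label(arr, structure=_structure(arr.ndim, connectivity))
    if n == 0:
        import warnings

        warnings.warn("keep_largest_component called on an empty mask", stacklevel=2)
        return BinaryMask(arr.copy(), mask.meta)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    # ndimage.label assigns labels in raster-scan order, so argmax's
    # first-maximum rule implements the lexicographic tie-break
    winner = int(np.argmax(sizes))
    return BinaryMask(labels == winner, mask.meta)


def _disc_footprint(radius: int, ndim: int) -> np.ndarray:
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    d2 = sum(g.astype(np.int64) ** 2 for g in grids)
    return (d2 <= radius * radius).astype(np.int64)


def median_filter_mask(
    mask: BinaryMask, radius_px: int = DEFAULT_MEDIAN_RADIUS_PX
) -> BinaryMask:
    """Majority filter over a Euclidean disc (2D) or ball (3D) of given radius.

    Boundaries are handled by reflection; exact ties resolve to foreground.
    ``radius_px = 0`` is the identity.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be non-negative")
    if radius_px == 0:
        return BinaryMask(mask.values.copy(), mask.meta)
    arr = mask.values.astype(np.int64)
    fp = _disc_footprint(radius_px, arr.ndim)
    counts = ndimage.correlate(arr, fp, mode="reflect")
    out = 2 * counts >= int(fp.sum())
    return BinaryMask(out, mask.meta)


def postprocess_histology(
    mask: BinaryMask,
    min_size: int = DEFAULT_MIN_REGION_PX,
    median_radius_px: int = DEFAULT_MEDIAN_RADIUS_PX,
) -> BinaryMask:
    """Histology chain: small-region removal, then 2D median filtering."""
    if mask.ndim != 2:
        raise ValueError("histology post-processing expects a 2D mask")
    return median_filter_mask(remove_small_regions(mask, min_size), median_radius_px)


def postprocess_microct(
    mask: BinaryMask, median_radius_px: int = DEFAULT_MEDIAN_RADIUS_PX
) -> BinaryMask:
    """Micro-CT chain: largest-component sweep, then 3D median filtering."""
    if mask.ndim != 3:
        raise ValueError("micro-CT post-processing expects a 3D mask")
    return median_filter_mask(keep_largest_component(mask), median_radius_px)
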