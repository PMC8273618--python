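"""Reading and writing images, per-slice stacks, masks, and summary tables.

On-disk formats are deliberately plain: 8/16-bit PNG or TIFF for single
images, a directory of per-slice files for volumes (assembled in
lexicographic filename order), and RFC-4180 CSV for tabular summaries.
Intensities are rescaled to [0, 1] by the input bit-depth maximum on read;
masks are written as 0/255 8-bit images.
"""

from __future__ import annotations

import glob
import os
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .grids import BinaryMask, GridMetadata, Image2D, ImageVolume

_IMAGE_EXTS = (".png", ".tif", ".tiff")

SUMMARY_COLUMNS = [
    "sample_id",
    "region",
    "n_foreground",
    "mean_um",
    "median_um",
    "max_um",
    "sd_um",
    "pixel_size_um",
]


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0  # float images are assumed already scaled


def _to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance-free mean
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float64) / _dtype_max(arr)


def _list_slice_files(directory_or_pattern: str | os.PathLike) -> list[str]:
    p = Path(directory_or_pattern)
    if p.is_dir():
        files = [
            str(f)
            for f in p.iterdir()
            if f.suffix.lower() in _IMAGE_EXTS and f.is_file()
        ]
    else:
        files = glob.glob(str(directory_or_pattern))
    return sorted(files, key=lambda f: Path(f).name)


def read_image(path: str | os.PathLike, meta: GridMetadata | None = None) -> Image2D:
    """Read a single grayscale image, rescaled to [0, 1] by its bit-depth max."""
    arr = _to_unit(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return Image2D(arr, meta or GridMetadata())


def write_image(image: Image2D | np.ndarray, path: str | os.PathLike, bits: int = 8) -> None:
    arr = image.intensities if isinstance(image, Image2D) else np.asarray(image)
    if bits == 8:
        out = np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)
    elif bits == 16:
        out = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(path, out)


def read_image_stack(
    directory_or_pattern: str | os.PathLike,
    meta_defaults: GridMetadata | None = None,
) -> ImageVolume:
    """Assemble a volume from per-slice image files.

    Slices are stacked in lexicographic filename order (writers in this
    package zero-pad indices so lexicographic order equals numeric order).
    All slices must share one shape.
    """
    files = _list_slice_files(directory_or_pattern)
    if not files:
        raise FileNotFoundError(f"no slice images found under {directory_or_pattern}")
    slices = [_to_unit(iio.imread(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice shapes {sorted(shapes)} under {directory_or_pattern}")
    return ImageVolume(np.stack(slices, axis=0), meta_defaults or GridMetadata())


def read_mask(path: str | os.PathLike, meta: GridMetadata | None = None) -> BinaryMask:
    arr = iio.imread(path)
    return BinaryMask((np.asarray(arr) > 0).astype(np.uint8), meta or GridMetadata())


def read_mask_stack(
    directory_or_pattern: str | os.PathLike,
    meta_defaults: GridMetadata | None = None,
) -> BinaryMask:
    vol = read_image_stack(directory_or_pattern, meta_defaults)
    return BinaryMask((vol.intensities > 0).astype(np.uint8), vol.meta)


def write_mask(mask: BinaryMask | np.ndarray, path: str | os.PathLike) -> None:
    arr = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))


def write_mask_stack(
    mask: BinaryMask,
    directory: str | os.PathLike,
    prefix: str = "slice_",
    ext: str = ".png",
) -> list[Path]:
    """Write a 3D mask as one 0/255 8-bit image per slice.

    Filenames are zero-padded (``slice_0000.png`` ...) so a lexicographic
    re-read reproduces the slice order.
    """
    if mask.ndim != 3:
        raise ValueError("write_mask_stack expects a 3D mask")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    try:
        for i, sl in enumerate(mask.values):
            p = directory / f"{prefix}{i:04d}{ext}"
            iio.imwrite(p, sl.astype(np.uint8) * 255)
            paths.append(p)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing mask slice under {directory}: {exc}") from exc
    return paths


def write_stack(
    volume: ImageVolume,
    directory: str | os.PathLike,
    prefix: str = "slice_",
    ext: str = ".png",
    bits: int = 8,
) -> list[Path]:
    """Write an intensity volume as zero-padded per-slice files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(volume.intensities):
        p = directory / f"{prefix}{i:04d}{ext}"
        write_image(sl, p, bits=bits)
        paths.append(p)
    return paths


def write_summary_table(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write labelled thickness summaries to CSV.

    Each row is a mapping with the keys in :data:`SUMMARY_COLUMNS`
    (typically built with :func:`ccmorph.thickness.summary_row`).
    """
    df = pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_summary_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
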