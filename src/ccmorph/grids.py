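"""Core in-memory containers: images, volumes, masks, and their grid metadata.

Every array travels with a :class:`GridMetadata` carrying the physical pixel
size (isotropic, in micrometres) and a modality tag, so downstream thickness
summaries can be reported in µm without re-threading units through every call.

Axis conventions
----------------
* 2D images are ``(row, column)`` with the osteochondral depth axis along
  rows (cartilage at low row indices, bone at high row indices).
* 3D volumes are ``(slice, row, column)`` with depth along the slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Modality = Literal["histology", "microct"]

#: Default isotropic pixel sizes by modality (µm / pixel): desktop µCT scans
#: reconstructed at 3.2 µm and light-microscopy histology at 2.56 µm.
DEFAULT_PIXEL_SIZE_UM: dict[str, float] = {"microct": 3.2, "histology": 2.56}


@dataclass(frozen=True)
class GridMetadata:
    """Physical metadata shared by an image/volume and everything derived from it.

    Parameters
    ----------
    pixel_size_um
        Isotropic physical pixel size in micrometres; must be positive.
        When ``None``, the modality default is applied (3.2 µm for
        ``microct``, 2.56 µm for ``histology``).
    modality_tag
        Either ``"histology"`` or ``"microct"``.
    """

    pixel_size_um: float | None = None
    modality_tag: Modality = "microct"

    def __post_init__(self) -> None:
        if self.modality_tag not in DEFAULT_PIXEL_SIZE_UM:
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        if self.pixel_size_um is None:
            object.__setattr__(
                self, "pixel_size_um", DEFAULT_PIXEL_SIZE_UM[self.modality_tag]
            )
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    def with_pixel_size(self, pixel_size_um: float) -> "GridMetadata":
        return replace(self, pixel_size_um=pixel_size_um)


def _check_unit_interval(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError(f"{name} intensities must lie in [0, 1]")


@dataclass
class Image2D:
    """A single grayscale image with intensities scaled to [0, 1]."""

    intensities: np.ndarray
    meta: GridMetadata = field(default_factory=GridMetadata)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        _check_unit_interval(self.intensities, "Image2D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class ImageVolume:
    """A grayscale image stack ``(slice, row, column)`` scaled to [0, 1]."""

    intensities: np.ndarray
    meta: GridMetadata = field(default_factory=GridMetadata)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if self.intensities.shape[0] < 1:
            raise ValueError("ImageVolume requires at least one slice")
        _check_unit_interval(self.intensities, "ImageVolume")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class BinaryMask:
    """A strictly binary labelling on the same grid as its source image."""

    values: np.ndarray
    meta: GridMetadata = field(default_factory=GridMetadata)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("BinaryMask values must be strictly 0/1")
        self.values = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def foreground_count(self) -> int:
        return int(self.values.sum())
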