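"""Whole-image and whole-volume prediction by tiled sliding windows.

Large images are covered with overlapping fixed-size windows (default
512 x 1024 pixels advancing by 256 x 512), each tile is pushed through the
network, and overlapping predictions are averaged with uniform weights.
The final row/column of windows is shifted inward so windows never leave
the image; images smaller than one window are reflect-padded up to window
size and cropped after stitching. Volumes are predicted slice-by-slice
along the coronal and sagittal planes and all (fold x plane) probability
maps are averaged uniformly into the final map, which is then thresholded
(default 0.8 — deliberately high, to exclude ambiguous areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .grids import BinaryMask, GridMetadata, Image2D, ImageVolume

DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class TileSpec:
    window: tuple[int, int] = (512, 1024)
    step: tuple[int, int] = (256, 512)

    def __post_init__(self) -> None:
        for w, s in zip(self.window, self.step):
            if not (0 < s <= w):
                raise ValueError(f"step must satisfy 0 < step <= window, got {self.step} vs {self.window}")


@dataclass
class ProbabilityMap:
    values: np.ndarray
    meta: GridMetadata = field(default_factory=GridMetadata)
    n_folds: int = 1
    planes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = v

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class InferenceConfig:
    tiles: TileSpec = TileSpec()
    threshold: float = DEFAULT_THRESHOLD
    planes: tuple[str, ...] = ("coronal", "sagittal")

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not self.planes:
            raise ValueError("at least one plane is required")
        for p in self.planes:
            if p not in ("coronal", "sagittal"):
                raise ValueError(f"unknown plane {p!r}")


def _axis_origins(extent: int, window: int, step: int) -> list[int]:
    """Window origins along one axis: regular steps plus an inward-shifted
    final origin so the last window ends exactly at the boundary."""
    origins = list(range(0, extent - window + 1, step))
    last = extent - window
    if origins[-1] != last:
        origins.append(last)
    return origins


def tile_image(image: np.ndarray | Image2D, tiles: TileSpec = TileSpec()):
    """Cover an image with sliding windows.

    Returns ``(tile_list, origins, pad)`` where ``tile_list[i]`` is the
    window content at ``origins[i]`` (coordinates in the padded frame) and
    ``pad`` is the reflect-padding applied when the image is smaller than
    one window (``(0, 0)`` otherwise). Together the windows cover every
    pixel.
    """
    arr = image.intensities if isinstance(image, Image2D) else np.asarray(image)
    wr, wc = tiles.window
    pr = max(wr - arr.shape[0], 0)
    pc = max(wc - arr.shape[1], 0)
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="reflect")
    origins = [
        (r, c)
        for r in _axis_origins(arr.shape[0], wr, tiles.step[0])
        for c in _axis_origins(arr.shape[1], wc, tiles.step[1])
    ]
    tile_list = [arr[r : r + wr, c : c + wc] for r, c in origins]
    return tile_list, origins, (pr, pc)


def stitch(
    tile_preds: Sequence[np.ndarray],
    origins: Sequence[tuple[int, int]],
    shape: tuple[int, int],
    pad: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Average overlapping tile predictions into a full-size map.

    ``shape`` is the original (unpadded) image shape; every pixel must be
    covered by at least one tile or an internal error is raised.
    """
    padded_shape = (shape[0] + pad[0], shape[1] + pad[1])
    acc = np.zeros(padded_shape, dtype=np.float64)
    cover = np.zeros(padded_shape, dtype=np.int64)
    for pred, (r, c) in zip(tile_preds, origins):
        pred = np.asarray(pred, dtype=np.float64)
        acc[r : r + pred.shape[0], c : c + pred.shape[1]] += pred
        cover[r : r + pred.shape[0], c : c + pred.shape[1]] += 1
    if (cover == 0).any():
        raise RuntimeError("internal error: tiling left pixels uncovered")
    out = acc / cover
    return out[: shape[0], : shape[1]]


def _predict_one_model(image_arr: np.ndarray, model, tiles: TileSpec) -> np.ndarray:
    tile_list, origins, pad = tile_image(image_arr, tiles)
    preds = [model.predict(t) for t in tile_list]
    return stitch(preds, origins, image_arr.shape, pad)


def predict_2d(
    image: Image2D | np.ndarray,
    checkpoints: Sequence,
    cfg: InferenceConfig = InferenceConfig(),
) -> ProbabilityMap:
    """Fold-ensemble probability map for a single 2D image.

    ``checkpoints`` is a sequence of model handles (or checkpoint paths);
    the stitched per-fold maps are averaged uniformly.
    """
    models = _resolve_models(checkpoints)
    arr = image.intensities if isinstance(image, Image2D) else np.asarray(image, dtype=np.float64)
    maps = [_predict_one_model(arr, m, cfg.tiles) for m in models]
    meta = image.meta if isinstance(image, Image2D) else GridMetadata()
    return ProbabilityMap(np.mean(maps, axis=0), meta, n_folds=len(models))


def predict_volume(
    volume: ImageVolume | np.ndarray,
    checkpoints: Sequence,
    cfg: InferenceConfig = InferenceConfig(),
) -> ProbabilityMap:
    """Fold- and plane-ensemble probability map for a volume.

    For each requested plane the volume is predicted slice-by-slice with
    2D tiling (coronal = fixed row axis, sagittal = fixed column axis of a
    ``(slice, row, column)`` volume), the per-slice maps are reassembled,
    and the final map is the uniform mean over every (plane, fold) member.
    """
    models = _resolve_models(checkpoints)
    arr = volume.intensities if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=np.float64)
    meta = volume.meta if isinstance(volume, ImageVolume) else GridMetadata()
    member_maps = []
    for plane in cfg.planes:
        axis = {"coronal": 1, "sagittal": 2}[plane]
        for m in models:
            out = np.empty_like(arr)
            for i in range(arr.shape[axis]):
                sl = np.take(arr, i, axis=axis)
                pred = _predict_one_model(sl, m, cfg.tiles)
                if axis == 1:
                    out[:, i, :] = pred
                else:
                    out[:, :, i] = pred
            member_maps.append(out)
    return ProbabilityMap(
        np.mean(member_maps, axis=0), meta, n_folds=len(models), planes=tuple(cfg.planes)
    )


def threshold_probability(
    pmap: ProbabilityMap | np.ndarray, t: float = DEFAULT_THRESHOLD
) -> BinaryMask:
    """Binarize a probability map at ``t`` (inclusive: value >= t is CC)."""
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1)")
    arr = pmap.values if isinstance(pmap, ProbabilityMap) else np.asarray(pmap)
    meta = pmap.meta if isinstance(pmap, ProbabilityMap) else GridMetadata()
    return BinaryMask(arr >= t, meta)


def _resolve_models(checkpoints: Sequence) -> list:
    from .model import load_checkpoint

    if not checkpoints:
        raise ValueError("at least one checkpoint or model handle is required")
    models = []
    for ck in checkpoints:
        if isinstance(ck, (str, Path)):
            models.append(load_checkpoint(ck))
        elif hasattr(ck, "predict"):
            models.append(ck)
        else:
            raise TypeError(f"cannot interpret checkpoint {ck!r}")
    return models
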