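"""Core data types and TIFF I/O for labeled instance masks and image stacks.

A labeled mask is a 2D non-negative integer image in which 0 is background
and each positive value identifies one cell instance. Labels are opaque IDs
assigned by the upstream segmenter: they need not be contiguous, and a
label's pixel set need not be connected (real model outputs can be
fragmented). Masks travel as multi-page TIFF, one page per frame, exactly
as segmentation tools export them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabeledMask",
    "ImageStack",
    "MaskMovie",
    "MaskFormatError",
    "read_mask_tiff",
    "write_mask_tiff",
    "read_stack_tiff",
    "object_inventory",
]

#: Maximum number of channels the classifier framework accepts.
MAX_CHANNELS = 6


class MaskFormatError(ValueError):
    """Raised when a file or array does not satisfy the mask contract."""


@dataclass(frozen=True)
class LabeledMask:
    """One frame of instance segmentation.

    Parameters
    ----------
    pixels
        2D array of non-negative integers; 0 is background, each positive
        value labels one cell instance.
    frame_index
        Position of this frame within its movie.
    pixel_size
        Physical edge length of one pixel in micrometres. Metadata only.
    """

    pixels: np.ndarray
    frame_index: int = 0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MaskFormatError(f"mask must be 2D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise MaskFormatError(f"mask must have integer dtype, got {px.dtype}")
        if px.size and px.min() < 0:
            raise MaskFormatError("mask contains negative labels")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of the distinct positive labels present."""
        u = np.unique(self.pixels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMask):
            return NotImplemented
        return (
            self.frame_index == other.frame_index
            and self.pixels.shape == other.pixels.shape
            and bool(np.array_equal(self.pixels, other.pixels))
        )


@dataclass(frozen=True)
class ImageStack:
    """A multi-channel image frame (brightfield plus fluorescence channels).

    All channels share the same height/width; at most 6 channels are
    accepted, matching the classifier framework limit.
    """

    channels: tuple[np.ndarray, ...]
    channel_names: tuple[str, ...] = ()
    frame_index: int = 0

    def __post_init__(self) -> None:
        chans = tuple(np.asarray(c, dtype=np.float64) for c in self.channels)
        if not 1 <= len(chans) <= MAX_CHANNELS:
            raise MaskFormatError(
                f"stack must have 1-{MAX_CHANNELS} channels, got {len(chans)}"
            )
        shapes = {c.shape for c in chans}
        if len(shapes) != 1 or chans[0].ndim != 2:
            raise MaskFormatError(f"channels must be 2D and share a shape, got {shapes}")
        names = tuple(self.channel_names) or tuple(
            f"ch{i}" for i in range(len(chans))
        )
        if len(names) != len(chans):
            raise MaskFormatError("channel_names length must match channel count")
        object.__setattr__(self, "channels", chans)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        """Channels stacked along the last axis, shape (H, W, C)."""
        return np.stack(self.channels, axis=-1)


@dataclass(frozen=True)
class MaskMovie:
    """An ordered sequence of labeled mask frames of identical shape."""

    frames: tuple[LabeledMask, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if frames:
            idx = [f.frame_index for f in frames]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise MaskFormatError("frame indices must be strictly increasing")
            shapes = {f.shape for f in frames}
            if len(shapes) != 1:
                raise MaskFormatError(f"all frames must share a shape, got {shapes}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> LabeledMask:
        return self.frames[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskMovie):
            return NotImplemented
        return len(self) == len(other) and all(
            a == b for a, b in zip(self.frames, other.frames)
        )

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.frames[0].shape if self.frames else None


def read_mask_tiff(path: str | Path) -> MaskMovie:
    """Read a multi-page TIFF of labeled masks, one page per frame.

    Pixel values are preserved bit-exactly; labels are never remapped.

    Raises
    ------
    MaskFormatError
        If the file has a non-integer sample format or contains no pages.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (FileNotFoundError, OSError):
        raise
    except Exception as exc:  # malformed TIFF
        raise MaskFormatError(f"cannot read {path} as TIFF: {exc}") from exc
    arr = np.asarray(pages)
    if arr.size == 0:
        raise MaskFormatError(f"{path} contains no image data")
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskFormatError(
            f"mask TIFF must have integer sample format, got {arr.dtype}"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise MaskFormatError(f"expected 2D pages, got array of shape {arr.shape}")
    return MaskMovie(tuple(LabeledMask(p, frame_index=i) for i, p in enumerate(arr)))


def _dtype_for_labels(max_label: int, dtype: np.dtype | None) -> np.dtype:
    if dtype is not None:
        dt = np.dtype(dtype)
        if not np.issubdtype(dt, np.integer):
            raise MaskFormatError(f"mask dtype must be integer, got {dt}")
        if max_label > np.iinfo(dt).max:
            raise MaskFormatError(
                f"label {max_label} exceeds the maximum of dtype {dt} "
                f"({np.iinfo(dt).max}); refusing silent wraparound"
            )
        return dt
    for cand in (np.uint8, np.uint16, np.uint32):
        if max_label <= np.iinfo(cand).max:
            return np.dtype(cand)
    raise MaskFormatError(f"label {max_label} exceeds 32-bit TIFF range")


def write_mask_tiff(
    movie: MaskMovie | LabeledMask,
    path: str | Path,
    dtype: np.dtype | str | None = None,
) -> None:
    """Write masks as a multi-page integer TIFF, one page per frame.

    The bit depth is chosen automatically (8/16/32-bit unsigned) unless
    ``dtype`` is given. A label that does not fit the chosen depth raises
    an error; labels are never wrapped.
    """
    if isinstance(movie, LabeledMask):
        movie = MaskMovie((movie,))
    if len(movie) == 0:
        raise MaskFormatError("refusing to write an empty movie")
    max_label = max(int(f.pixels.max(initial=0)) for f in movie)
    dt = _dtype_for_labels(max_label, None if dtype is None else np.dtype(dtype))
    data = np.stack([f.pixels.astype(dt) for f in movie])
    tifffile.imwrite(Path(path), data)


def read_stack_tiff(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    frame_index: int = 0,
) -> ImageStack:
    """Read a channel-major multi-page TIFF as one multi-channel frame."""
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise MaskFormatError(f"expected channel-major pages, got shape {arr.shape}")
    names = tuple(channel_names) if channel_names is not None else ()
    return ImageStack(tuple(arr), channel_names=names, frame_index=frame_index)


def object_inventory(mask: LabeledMask) -> pd.DataFrame:
    """Tabulate every object in a mask: label, pixel area, centroid.

    The centroid is the unweighted mean of the object's (row, col) pixel
    coordinates — first-order binary moments, 0-based, pixel centers at
    integer coordinates. An empty mask yields an empty table.
    """
    px = mask.pixels
    labels = mask.labels
    if labels.size == 0:
        return pd.DataFrame(
            {"label": pd.Series([], dtype=np.int64),
             "area_px": pd.Series([], dtype=np.int64),
             "centroid_row": pd.Series([], dtype=float),
             "centroid_col": pd.Series([], dtype=float)}
        )
    flat = px.ravel()
    nz = np.flatnonzero(flat)
    vals = flat[nz]
    rows, cols = np.unravel_index(nz, px.shape)
    order = np.searchsorted(labels, vals)
    area = np.bincount(order, minlength=labels.size)
    rsum = np.bincount(order, weights=rows, minlength=labels.size)
    csum = np.bincount(order, weights=cols, minlength=labels.size)
    return pd.DataFrame(
        {
            "label": labels.astype(np.int64),
            "area_px": area.astype(np.int64),
            "centroid_row": rsum / area,
            "centroid_col": csum / area,
        }
    )
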