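"""Raster input and binarization.

Scanned tracings arrive as PNG or TIFF, grayscale or RGB.  They are reduced
to a float intensity array in [0, 1] and then to a boolean ink mask, either
with Otsu's histogram threshold (default — the workflow names no fixed
threshold) or with a user-supplied fixed cut.  Ink is assumed dark on a light
background (pen on a transparent sheet over white backing); ``dark_foreground=False``
inverts the convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, ImageFormatError, InvalidParameterError

__all__ = ["TraceImage", "BinaryImage", "load_image", "binarize"]

_SUPPORTED_FORMATS = {"PNG", "TIFF"}

# ITU-R BT.601 luminance weights, matching common scanner/grayscale exports
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class TraceImage:
    """A grayscale raster with intensities normalized to [0, 1].

    ``resolution_hint`` carries a known pixel scale (px/cm) when one is
    available, e.g. from the synthetic renderer; the calibration stage never
    requires it.
    """

    pixels: np.ndarray
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InvalidParameterError("pixels must be a non-empty 2-D array")
        self.pixels = p

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryImage:
    """Boolean ink mask; ``dark_foreground`` records the ink polarity used."""

    mask: np.ndarray
    dark_foreground: bool = True
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def load_image(path: str | Path) -> TraceImage:
    """Load a PNG/TIFF image as a normalized grayscale :class:`TraceImage`.

    RGB(A) input is converted by BT.601 luminance weighting; intensities are
    scaled to [0, 1] from the native bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            fmt = im.format
            if fmt not in _SUPPORTED_FORMATS:
                raise ImageFormatError(
                    f"unsupported format {fmt!r} for {path}; expected PNG or TIFF"
                )
            raw = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot read image file: {path}") from exc

    arr = raw.astype(float)
    if arr.ndim == 3:
        arr = arr[:, :, :3] @ _LUMA
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    else:  # float TIFF: assume already [0, 1]
        arr = np.clip(arr, 0.0, 1.0)
    return TraceImage(pixels=arr)


def binarize(
    img: TraceImage,
    method: str = "otsu",
    threshold: float | None = None,
    dark_foreground: bool = True,
) -> BinaryImage:
    """Threshold an intensity image into an ink mask.

    ``method='otsu'`` derives the cut from the intensity histogram and fails
    with :class:`DegenerateImageError` on a constant image; ``method='fixed'``
    requires ``threshold`` strictly inside (0, 1).  Foreground means ink:
    intensities below the cut when ``dark_foreground`` (default), above it
    otherwise.
    """
    p = img.pixels
    if method == "otsu":
        if np.ptp(p) == 0:
            raise DegenerateImageError(
                "cannot apply Otsu thresholding to a constant-intensity image"
            )
        thr = float(threshold_otsu(p))
    elif method == "fixed":
        if threshold is None or not 0.0 < threshold < 1.0:
            raise InvalidParameterError(
                "fixed binarization requires a threshold in (0, 1)"
            )
        thr = float(threshold)
    else:
        raise InvalidParameterError(f"unknown binarization method {method!r}")

    mask = p < thr if dark_foreground else p > thr
    return BinaryImage(mask=mask, dark_foreground=dark_foreground, threshold=thr)
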