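"""Wound-interior extraction from a binarized tracing.

The automated pipeline mirrors the manual scan-processing workflow: the scan
is binarized, the straight centimetric rules are erased, small pen gaps are
closed, the exterior is flood-painted from the image border, and whatever
closed region remains inside the drawn boundary is the wound interior.  The
interior is measured to the *inner* rim of the pen stroke (the stroke itself
is never interior), which makes the area estimate conservative by up to one
stroke width.

Connectivity: ink uses 8-connectivity (diagonal pen strokes stay connected)
while the exterior flood fill uses 4-connectivity (it cannot leak through a
diagonal joint) — the standard duality that prevents both leakage and false
openings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .calibration import Calibration, detect_grid_scale, px_area_to_cm2
from .errors import (
    AmbiguousInteriorError,
    InvalidParameterError,
    OpenBoundaryError,
    WoundPlanimError,
)
from .image_io import BinaryImage, TraceImage, binarize
from .synthetic import GridSpec

__all__ = [
    "WoundMask",
    "SegmentOptions",
    "remove_grid_lines",
    "close_boundary",
    "fill_exterior",
    "segment",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element
_S4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class WoundMask:
    """Binary wound interior at a known pixel scale.

    ``mask`` is True on interior pixels only (never on the pen stroke);
    ``provenance`` records the processing steps that produced it.
    """

    mask: np.ndarray
    cal: Calibration
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentOptions:
    """Tunables of the end-to-end segmentation pipeline.

    ``max_gap`` (cm) is the largest pen gap bridged before filling — it also
    re-closes the boundary where a stroke running almost parallel to a grid
    rule was cut during rule removal, so it should stay a few multiples of
    the rule thickness;
    ``min_interior_cm2`` is the smallest enclosed region treated as a
    candidate wound (smaller specks are ignored); ``deskew_above_deg``
    triggers a resampling deskew when the detected grid angle exceeds it.
    """

    binarize_method: str = "otsu"
    threshold: float | None = None
    dark_foreground: bool = True
    max_gap: float = 0.25
    min_interior_cm2: float = 0.1
    deskew_above_deg: float = 3.0


def _opening_1d(mask: np.ndarray, length: int, axis: int) -> np.ndarray:
    """Binary opening with a 1-D line structuring element (fast, separable)."""
    u = mask.astype(np.uint8)
    eroded = ndimage.minimum_filter1d(u, size=length, axis=axis, mode="constant", cval=0)
    opened = ndimage.maximum_filter1d(eroded, size=length, axis=axis, mode="constant", cval=0)
    return opened.astype(bool)


def remove_grid_lines(binary: BinaryImage, cal: Calibration) -> BinaryImage:
    """Erase the straight centimetric rules, preserving the curved pen trace.

    Long axis-aligned runs are detected with line structuring elements of
    length 1.6x the calibrated cell spacing — rules span the whole sheet, so
    they survive an opening that long, while a pen stroke running tangent to
    a rule cannot (a wound-scale curve of curvature radius R and stroke
    width w stays within one pixel row for only ~2*sqrt(2*R*w) px, well
    under 1.6 cells at any plausible R).  When the
    calibration carries detected rule positions and the deskew angle is
    negligible, detection is further restricted to narrow bands around those
    positions.  Trace pixels deleted where the pen crosses a rule are
    restored if they fall inside a small morphological closing of the
    surviving trace: the closing bridges the cut stroke across the rule at
    any crossing angle, but never reaches sideways onto the rule stubs
    flanking the stroke, which stay deleted.  Grid-free input passes through
    unchanged.
    """
    mask = binary.mask
    spacing_x = cal.px_per_cm_x  # rule spacing in px for 1 cm cells
    spacing_y = cal.px_per_cm_y
    if cal.x_lines_px is not None and cal.x_lines_px.size >= 2:
        spacing_x = float(np.median(np.diff(cal.x_lines_px)))
    if cal.y_lines_px is not None and cal.y_lines_px.size >= 2:
        spacing_y = float(np.median(np.diff(cal.y_lines_px)))

    len_h = max(9, int(round(1.6 * spacing_x)))  # horizontal rules run along x
    len_v = max(9, int(round(1.6 * spacing_y)))
    lines_h = _opening_1d(mask, len_h, axis=1)
    lines_v = _opening_1d(mask, len_v, axis=0)

    # restrict to bands around the known rule positions when available and
    # the raster is not rotated (bands are meaningless under rotation)
    if abs(cal.grid_angle) <= 0.5:
        band = 4
        if cal.y_lines_px is not None and cal.y_lines_px.size:
            rows = np.arange(mask.shape[0])
            hit = np.any(
                np.abs(rows[None, :] - cal.y_lines_px[:, None]) <= band, axis=0
            )
            lines_h &= hit[:, None]
        if cal.x_lines_px is not None and cal.x_lines_px.size:
            colidx = np.arange(mask.shape[1])
            hit = np.any(
                np.abs(colidx[None, :] - cal.x_lines_px[:, None]) <= band, axis=0
            )
            lines_v &= hit[None, :]

    grid_mask = lines_h | lines_v
    trace = mask & ~grid_mask

    # restore crossings: removed pixels bridged by a closing of the surviving
    # trace.  The radius must bridge not only perpendicular crossings (gap =
    # rule thickness) but also the broken stretches left where the stroke
    # runs almost parallel to a rule; restoration stays confined to removed
    # rule pixels, so it cannot thicken the stroke elsewhere.
    removed = mask & grid_mask
    restore = removed & _disk_closing(trace, 12.0)

    return BinaryImage(
        mask=trace | restore,
        dark_foreground=binary.dark_foreground,
        threshold=binary.threshold,
    )


def _disk_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological closing with a Euclidean disk, via distance transforms."""
    if radius_px <= 0:
        return mask
    dilated = ndimage.distance_transform_edt(~mask) <= radius_px
    return ndimage.distance_transform_edt(dilated) > radius_px


def close_boundary(binary: BinaryImage, max_gap: float, cal: Calibration) -> BinaryImage:
    """Bridge pen gaps up to ``max_gap`` cm by disk closing; no-op at 0."""
    if max_gap < 0:
        raise InvalidParameterError("max_gap must be >= 0")
    if max_gap == 0:
        return binary
    radius_px = max_gap / 2.0 * (cal.px_per_cm_x + cal.px_per_cm_y) / 2.0
    closed = _disk_closing(binary.mask, radius_px)
    # closing may not shrink the ink: keep the original stroke pixels too
    return BinaryImage(
        mask=closed | binary.mask,
        dark_foreground=binary.dark_foreground,
        threshold=binary.threshold,
    )


def fill_exterior(binary: BinaryImage, cal: Calibration) -> WoundMask:
    """Paint the exterior from the border and return the enclosed interior.

    Non-ink pixels 4-connected to the image border form the exterior;
    whatever non-ink pixels remain are enclosed by the trace.  Exactly one
    enclosed component larger than a minimal speck size must exist.

    Raises
    ------
    OpenBoundaryError
        If no enclosed region exists (open or missing curve).
    AmbiguousInteriorError
        If two or more enclosed regions each exceed the minimum size (for
        example nested rings yielding an annulus plus a core).
    """
    return _fill_exterior(binary, cal)


def _fill_exterior(
    binary: BinaryImage, cal: Calibration, min_interior_cm2: float = 0.1
) -> WoundMask:
    ink = binary.mask
    labels, n = ndimage.label(~ink, structure=_S4)
    if n == 0:
        raise OpenBoundaryError("image is entirely ink; no interior exists")
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    interior_ids = [
        i for i in range(1, n + 1) if i not in set(border_labels.tolist())
    ]
    if not interior_ids:
        raise OpenBoundaryError(
            "the traced boundary does not enclose any region (open curve?)"
        )
    areas = {i: px_area_to_cm2(int(counts[i]), cal) for i in interior_ids}
    big = [i for i in interior_ids if areas[i] >= min_interior_cm2]
    if not big:
        raise OpenBoundaryError(
            "only speck-sized enclosed regions found; boundary likely open"
        )
    if len(big) > 1:
        raise AmbiguousInteriorError(
            f"{len(big)} enclosed regions exceed {min_interior_cm2} cm^2: "
            + ", ".join(f"{areas[i]:.2f} cm^2" for i in big),
            areas_cm2=[areas[i] for i in big],
        )
    mask = labels == big[0]
    return WoundMask(mask=mask, cal=cal, provenance=["fill_exterior"])


def segment(
    img: TraceImage,
    grid: GridSpec = GridSpec(),
    options: SegmentOptions = SegmentOptions(),
) -> WoundMask:
    """Run the full pipeline: binarize, calibrate, de-grid, close, fill.

    When the detected grid angle exceeds ``options.deskew_above_deg`` the
    grayscale image is resampled upright and re-binarized before grid removal;
    smaller angles are only reported in the calibration.  Stage failures are
    re-raised with the failing stage name attached as a note.
    """
    provenance: list[str] = []

    def _stage(name: str, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except WoundPlanimError as exc:
            exc.add_note(f"segmentation stage: {name}")
            raise
        provenance.append(name)
        return out

    binary = _stage(
        "binarize",
        binarize,
        img,
        method=options.binarize_method,
        threshold=options.threshold,
        dark_foreground=options.dark_foreground,
    )
    cal = _stage("detect_grid_scale", detect_grid_scale, binary, grid)

    if abs(cal.grid_angle) > options.deskew_above_deg:
        upright = _sk_rotate(
            img.pixels, -cal.grid_angle, order=1, mode="constant",
            cval=1.0, preserve_range=True,
        )
        provenance.append(f"deskew({cal.grid_angle:.2f} deg)")
        binary = _stage(
            "binarize",
            binarize,
            TraceImage(pixels=upright, resolution_hint=img.resolution_hint),
            method=options.binarize_method,
            threshold=options.threshold,
            dark_foreground=options.dark_foreground,
        )
        cal = _stage("detect_grid_scale", detect_grid_scale, binary, grid)

    binary = _stage("remove_grid_lines", remove_grid_lines, binary, cal)
    binary = _stage("close_boundary", close_boundary, binary, options.max_gap, cal)
    wound = _stage(
        "fill_exterior", _fill_exterior, binary, cal, options.min_interior_cm2
    )
    wound.provenance = provenance
    return wound
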