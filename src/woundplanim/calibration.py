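"""Automatic pixel-scale calibration from the ruled centimetric grid.

The measurement sheet carries 1 cm rules in both axes, so the pixel scale can
be recovered from the image itself instead of asking the user what 1 cm is:
the ink is projected onto each axis (after searching a small deskew angle),
grid rules appear as tall narrow peaks in the projection profiles, and the
scale is the median inter-peak spacing divided by the cell size.  The two
axes are estimated independently, so anisotropic pixels are handled.

The deskew angle is only *reported* here; resampling decisions belong to the
segmentation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidParameterError, NoGridError, UnreliableGridError
from .image_io import BinaryImage
from .synthetic import GridSpec

__all__ = ["Calibration", "detect_grid_scale", "px_area_to_cm2"]

_MIN_LINES = 4
_MAX_SPACING_CV = 0.20
_MAX_ANGLE_DEG = 8.0
# cap on pixels fed to the angle scan; keeps the scan fast on large scans
_ANGLE_SCAN_MAX_PX = 150_000


@dataclass
class Calibration:
    """Pixel scale and grid orientation estimated from the sheet's rules.

    ``grid_angle`` is the rotation (degrees, counter-clockwise) of the grid
    relative to the raster axes; ``residual`` is the RMS deviation of the
    detected line spacings from their median, in px.  ``x_lines_px`` /
    ``y_lines_px`` hold the detected rule positions in the deskewed pixel
    frame (vertical rules / horizontal rules respectively).
    """

    px_per_cm_x: float
    px_per_cm_y: float
    grid_angle: float = 0.0
    residual: float = 0.0
    x_lines_px: np.ndarray | None = field(default=None, repr=False)
    y_lines_px: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.px_per_cm_x <= 0 or self.px_per_cm_y <= 0:
            raise InvalidParameterError("px_per_cm must be positive")
        if abs(self.grid_angle) > 10.0:
            raise InvalidParameterError("grid_angle outside the +/-10 degree range")
        if self.residual < 0:
            raise InvalidParameterError("residual must be >= 0")

    def pixel_area_cm2(self) -> float:
        """Physical area of one pixel in cm^2."""
        return 1.0 / (self.px_per_cm_x * self.px_per_cm_y)

    def to_dict(self) -> dict:
        return {
            "px_per_cm_x": self.px_per_cm_x,
            "px_per_cm_y": self.px_per_cm_y,
            "grid_angle_deg": self.grid_angle,
            "residual_px": self.residual,
        }


def _rotated_coords(
    rows: np.ndarray, cols: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate pixel coordinates by ``-angle_deg`` about the origin.

    A grid drawn at +angle on the raster becomes axis-aligned in the
    returned (row', col') frame.
    """
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    # image-convention rotation (y down): undo a CCW rotation of the content
    r2 = c * rows - s * cols
    c2 = s * rows + c * cols
    return r2, c2


def _profile_sharpness(coords: np.ndarray) -> float:
    """Sum of squared histogram counts — maximal when lines align with bins."""
    shifted = coords - coords.min()
    h = np.bincount(shifted.astype(int))
    return float(np.sum(h.astype(float) ** 2))


def _estimate_angle(rows: np.ndarray, cols: np.ndarray) -> float:
    if rows.size > _ANGLE_SCAN_MAX_PX:
        step = rows.size // _ANGLE_SCAN_MAX_PX + 1
        rows = rows[::step]
        cols = cols[::step]

    def score(angle: float) -> float:
        r2, c2 = _rotated_coords(rows, cols, angle)
        return _profile_sharpness(r2) + _profile_sharpness(c2)

    def best_of(angles: np.ndarray) -> float:
        # the sharpness score is flat-topped near the optimum (histogram
        # binning), so among near-maximal scores prefer the smallest |angle|
        scores = np.array([score(a) for a in angles])
        near = scores >= (1.0 - 1e-3) * scores.max()
        candidates = angles[near]
        return float(candidates[np.argmin(np.abs(candidates))])

    coarse = np.arange(-_MAX_ANGLE_DEG, _MAX_ANGLE_DEG + 1e-9, 0.2)
    best = best_of(coarse)
    fine = best + np.arange(-12, 13) * 0.02  # includes `best` exactly
    return best_of(fine)


def _line_positions(coords: np.ndarray) -> np.ndarray:
    """Positions of grid rules along one axis from an ink projection profile.

    Rules project to narrow peaks whose height is of the order of the image
    extent; the pen trace spreads over many bins and stays far below the 30%
    prominence cut.  Peak centres are refined by an intensity-weighted
    centroid over +/-2 bins.
    """
    lo = np.floor(coords.min())
    shifted = coords - lo
    profile = np.bincount(shifted.astype(int)).astype(float)
    if profile.size < 3 or profile.max() <= 0:
        return np.array([])
    peaks, _ = find_peaks(
        np.pad(profile, 1), height=0.3 * profile.max(), distance=4
    )
    peaks = peaks - 1
    centers = []
    for p in peaks:
        sl = slice(max(p - 2, 0), min(p + 3, profile.size))
        w = profile[sl]
        idx = np.arange(sl.start, sl.stop)
        centers.append(float(np.sum(w * idx) / np.sum(w)))
    return np.asarray(centers) + lo


def detect_grid_scale(binary: BinaryImage, grid: GridSpec = GridSpec()) -> Calibration:
    """Estimate px/cm on both axes (and the deskew angle) from the grid rules.

    Raises
    ------
    NoGridError
        If fewer than 4 rules are detected on either axis.
    UnreliableGridError
        If the coefficient of variation of the rule spacings exceeds 20%.
    """
    mask = binary.mask
    rows, cols = np.nonzero(mask)
    if rows.size < 4 * min(mask.shape):
        # fewer ink pixels than four full-extent rules could ever produce
        raise NoGridError("image contains too little ink to hold a grid")
    rows = rows.astype(float)
    cols = cols.astype(float)

    align_angle = _estimate_angle(rows, cols)
    r2, c2 = _rotated_coords(rows, cols, align_angle)

    cal_axes = {}
    for name, coords in (("y", r2), ("x", c2)):
        centers = _line_positions(coords)
        if centers.size < _MIN_LINES:
            raise NoGridError(
                f"only {centers.size} grid lines detected on the {name} axis "
                f"(need >= {_MIN_LINES})"
            )
        spacings = np.diff(centers)
        med = float(np.median(spacings))
        cv = float(np.std(spacings) / np.mean(spacings))
        if cv > _MAX_SPACING_CV:
            raise UnreliableGridError(
                f"grid spacing varies too much on the {name} axis "
                f"(CV = {cv:.1%} > {_MAX_SPACING_CV:.0%})"
            )
        rms = float(np.sqrt(np.mean((spacings - med) ** 2)))
        cal_axes[name] = (med / grid.cell_size, rms, centers)

    sx, rms_x, x_centers = cal_axes["x"]
    sy, rms_y, y_centers = cal_axes["y"]
    return Calibration(
        px_per_cm_x=sx,
        px_per_cm_y=sy,
        # report the grid's own rotation (CCW positive), i.e. the angle the
        # alignment search had to undo
        grid_angle=-align_angle,
        residual=float(np.hypot(rms_x, rms_y) / np.sqrt(2)),
        x_lines_px=x_centers,
        y_lines_px=y_centers,
    )


def px_area_to_cm2(pixel_count: int, cal: Calibration) -> float:
    """Convert a pixel count to cm^2 using the anisotropic pixel scale."""
    if pixel_count < 0:
        raise InvalidParameterError("pixel_count must be >= 0")
    return pixel_count / (cal.px_per_cm_x * cal.px_per_cm_y)
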