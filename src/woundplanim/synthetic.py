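"""Synthetic wound-boundary traces with analytic ground truth.

Real inputs to this package are scans of a transparent centimetric ruler on
which a clinician has drawn the wound margin with a pen.  This module emulates
such scans: a sheet-sized raster carrying the 1 cm grid strokes plus a closed
boundary curve of configurable pen width, together with the exact (shoelace)
area and perimeter of the drawn curve.  Every downstream stage — binarization,
grid calibration, segmentation, measurement — can therefore be validated
against analytic truth without any external data.

Coordinate convention: continuous centimetre coordinates with the origin at
the sheet's top-left corner, x rightward, y downward.  The centre of pixel
(row i, col j) sits at ((j + 0.5) / res, (i + 0.5) / res), where ``res`` is
the rendering resolution in pixels per cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidParameterError, InvalidPolygonError, OutOfBoundsError
from .image_io import TraceImage

__all__ = [
    "GridSpec",
    "Polygon",
    "SyntheticTrace",
    "make_shape",
    "polygon_area",
    "polygon_perimeter",
    "render_trace",
    "save_trace",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the calibrated measurement sheet.

    Defaults describe a 22.0 x 17.0 cm sheet ruled into 1.0 cm^2 squares
    (374 cells in total); ``line_width`` is the printed stroke thickness of
    the grid rules in cm.
    """

    cell_size: float = 1.0
    sheet_width: float = 22.0
    sheet_height: float = 17.0
    line_width: float = 0.02

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidParameterError("cell_size must be positive")
        if self.sheet_width <= 0 or self.sheet_height <= 0:
            raise InvalidParameterError("sheet dimensions must be positive")
        if not 0 < self.line_width < self.cell_size / 4:
            raise InvalidParameterError(
                f"line_width must lie in (0, cell_size/4); got {self.line_width}"
            )

    @property
    def area_cm2(self) -> float:
        return self.sheet_width * self.sheet_height


@dataclass(frozen=True)
class Polygon:
    """Closed simple polygon in cm coordinates.

    Vertices are an (n, 2) float array of (x, y) points; the closing edge from
    the last vertex back to the first is implicit.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidPolygonError(
                f"polygon needs an (n>=3, 2) vertex array; got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in cm."""
        v = self.vertices
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()


def polygon_area(poly: Polygon) -> float:
    """Shoelace area of ``poly`` in cm^2, independent of orientation."""
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(poly: Polygon) -> float:
    """Total edge length of ``poly`` in cm, including the closing edge."""
    v = poly.vertices
    d = np.roll(v, -1, axis=0) - v
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def make_shape(
    kind: str,
    *,
    radius: float | None = None,
    a: float | None = None,
    b: float | None = None,
    mean_radius: float | None = None,
    amplitude: float = 0.15,
    smoothness: float = 1.0,
    center: tuple[float, float] = (11.0, 8.5),
    n_vertices: int = 256,
    seed: int = 0,
) -> Polygon:
    """Build a closed test shape as a polygon in cm coordinates.

    Parameters
    ----------
    kind
        ``circle`` (needs ``radius``), ``ellipse`` (needs semi-axes
        ``a >= b``), or ``blob`` (needs ``mean_radius``; an irregular but
        simple wound-like outline).
    amplitude, smoothness
        Blob only: total relative amplitude of the radial perturbation and
        the spectral decay exponent of its harmonics (larger = smoother).
    center
        Shape centre in cm; the default is the centre of the default sheet.
    n_vertices
        Boundary discretisation (>= 128 recommended).
    seed
        Seeds the blob's harmonic coefficients; circles/ellipses ignore it.

    The blob radius function is r(theta) = r0 * (1 + sum_k a_k sin(k theta
    + phi_k)) for k = 2..6, with the total perturbation capped at 60% of r0
    so the radius stays positive and the curve stays simple.
    """
    if n_vertices < 8:
        raise InvalidParameterError("n_vertices must be >= 8")
    cx, cy = center
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)

    if kind == "circle":
        if radius is None or radius <= 0:
            raise InvalidParameterError("circle needs radius > 0")
        r = np.full_like(theta, float(radius))
    elif kind == "ellipse":
        if a is None or b is None or b <= 0 or a < b:
            raise InvalidParameterError("ellipse needs semi-axes a >= b > 0")
        x = cx + a * np.cos(theta)
        y = cy + b * np.sin(theta)
        return Polygon(np.column_stack([x, y]))
    elif kind == "blob":
        if mean_radius is None or mean_radius <= 0:
            raise InvalidParameterError("blob needs mean_radius > 0")
        if amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        rng = np.random.default_rng(seed)
        ks = np.arange(2, 7)
        coeffs = rng.uniform(-1.0, 1.0, size=ks.size) / ks.astype(float) ** smoothness
        phases = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)
        total = np.sum(np.abs(coeffs))
        if total > 0:
            coeffs = coeffs / total * min(amplitude, 0.6)
        pert = np.sum(
            coeffs[:, None] * np.sin(ks[:, None] * theta[None, :] + phases[:, None]),
            axis=0,
        )
        r = mean_radius * (1.0 + pert)
    else:
        raise InvalidParameterError(f"unknown shape kind {kind!r}")

    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    return Polygon(np.column_stack([x, y]))


@dataclass
class SyntheticTrace:
    """A rendered trace plus the analytic truth it was rendered from.

    ``stroke_mask`` and ``grid_mask`` expose the exact pixels of the pen
    stroke and of the grid rules, so intermediate pipeline stages (grid
    removal, binarization) can be checked against the renderer itself.
    """

    image: TraceImage
    truth_polygon: Polygon | None
    truth_area: float | None
    truth_perimeter: float | None
    resolution: float
    trace_width: float
    seed: int
    grid: GridSpec
    stroke_mask: np.ndarray = field(repr=False, default=None)
    grid_mask: np.ndarray = field(repr=False, default=None)


def _grid_pixel_mask(grid: GridSpec, res: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the grid rules for an image of the given pixel shape."""
    h, w = shape
    half = grid.line_width / 2.0
    xc = (np.arange(w) + 0.5) / res
    yc = (np.arange(h) + 0.5) / res
    nx = int(np.floor(grid.sheet_width / grid.cell_size + 1e-9))
    ny = int(np.floor(grid.sheet_height / grid.cell_size + 1e-9))
    x_lines = np.arange(nx + 1) * grid.cell_size
    y_lines = np.arange(ny + 1) * grid.cell_size
    # epsilon guards exact pixel-boundary ties; every rule renders >= 1 px
    def _hits(centers: np.ndarray, lines: np.ndarray) -> np.ndarray:
        hit = np.zeros(centers.size, dtype=bool)
        for g in lines:
            d = np.abs(centers - g)
            near = d <= half + 1e-9
            if not near.any():
                near[np.argmin(d)] = True
            hit |= near
        return hit

    col_hit = _hits(xc, x_lines)
    row_hit = _hits(yc, y_lines)
    mask = np.zeros(shape, dtype=bool)
    mask[row_hit, :] = True
    mask[:, col_hit] = True
    return mask


def _stroke_pixel_mask(
    poly: Polygon, res: float, trace_width: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixels whose centre lies within trace_width/2 of the polygon path."""
    v = poly.vertices
    closed = np.vstack([v, v[:1]])
    # densely resample the path so every crossed pixel receives a sample
    pts = []
    for p, q in zip(closed[:-1], closed[1:]):
        seg_px = np.hypot(*(q - p)) * res
        n = max(int(np.ceil(seg_px * 3)), 2)
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        pts.append(p[None, :] + t[:, None] * (q - p)[None, :])
    pts = np.vstack(pts)
    rows = np.clip(np.round(pts[:, 1] * res - 0.5).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(pts[:, 0] * res - 0.5).astype(int), 0, shape[1] - 1)
    path = np.zeros(shape, dtype=bool)
    path[rows, cols] = True
    half_px = trace_width * res / 2.0
    if half_px <= 0.5:
        return path
    dist = ndimage.distance_transform_edt(~path)
    return dist <= half_px


def render_trace(
    poly: Polygon | None,
    grid: GridSpec = GridSpec(),
    resolution: float = 100.0,
    trace_width: float = 0.03,
    noise_sd: float = 0.0,
    seed: int = 0,
    antialias: bool = False,
) -> SyntheticTrace:
    """Render a grid sheet with an optional closed pen trace.

    Ink is dark (0.0) on a white (1.0) background.  With ``antialias`` off
    (the default) every pixel is fully ink or fully paper, so binarization of
    a noiseless render is exact.  ``poly=None`` renders the bare grid — a
    negative control for which downstream segmentation must fail with an
    open-boundary error.

    The ground truth refers to the polygon path itself (the stroke
    centreline), not to either rim of the rendered stroke.

    Raises
    ------
    InvalidParameterError
        If ``resolution`` < 20 px/cm or ``trace_width`` <= 0.
    OutOfBoundsError
        If the polygon does not fit on the sheet with >= 1 cell margin.
    """
    if resolution < 20:
        raise InvalidParameterError("resolution must be >= 20 px/cm")
    if trace_width <= 0:
        raise InvalidParameterError("trace_width must be positive")
    h = int(round(grid.sheet_height * resolution))
    w = int(round(grid.sheet_width * resolution))
    shape = (h, w)

    grid_mask = _grid_pixel_mask(grid, resolution, shape)
    if poly is not None:
        xmin, ymin, xmax, ymax = poly.bounds()
        m = grid.cell_size
        if (
            xmin < m
            or ymin < m
            or xmax > grid.sheet_width - m
            or ymax > grid.sheet_height - m
        ):
            raise OutOfBoundsError(
                "polygon must fit on the sheet with at least one cell margin"
            )
        stroke_mask = _stroke_pixel_mask(poly, resolution, trace_width, shape)
        truth_area = polygon_area(poly)
        truth_perimeter = polygon_perimeter(poly)
    else:
        stroke_mask = np.zeros(shape, dtype=bool)
        truth_area = None
        truth_perimeter = None

    image = np.ones(shape, dtype=float)
    if antialias and poly is not None:
        half_px = max(trace_width * resolution / 2.0, 0.5)
        path = _stroke_pixel_mask(poly, resolution, trace_width=0.0, shape=shape)
        dist = ndimage.distance_transform_edt(~path)
        # one-pixel linear ramp at the stroke rim
        image = np.clip(dist - half_px + 0.5, 0.0, 1.0)
        image[grid_mask] = 0.0
    else:
        image[grid_mask | stroke_mask] = 0.0

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + rng.normal(0.0, noise_sd, size=shape), 0.0, 1.0)

    timg = TraceImage(pixels=image, resolution_hint=resolution)
    return SyntheticTrace(
        image=timg,
        truth_polygon=poly,
        truth_area=truth_area,
        truth_perimeter=truth_perimeter,
        resolution=resolution,
        trace_width=trace_width,
        seed=seed,
        grid=grid,
        stroke_mask=stroke_mask,
        grid_mask=grid_mask,
    )


def save_trace(trace: SyntheticTrace, path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG plus a JSON sidecar with the truth fields.

    Returns the image path; the sidecar sits next to it with suffix
    ``.json``.
    """
    path = Path(path)
    arr = np.clip(np.round(trace.image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = {
        "truth_area_cm2": trace.truth_area,
        "truth_perimeter_cm": trace.truth_perimeter,
        "resolution_px_per_cm": trace.resolution,
        "trace_width_cm": trace.trace_width,
        "seed": trace.seed,
        "grid": {
            "cell_size_cm": trace.grid.cell_size,
            "sheet_width_cm": trace.grid.sheet_width,
            "sheet_height_cm": trace.grid.sheet_height,
            "line_width_cm": trace.grid.line_width,
        },
        "truth_polygon_cm": (
            trace.truth_polygon.vertices.tolist() if trace.truth_polygon else None
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path
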