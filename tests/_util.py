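"""Shared helpers for the test suite: direct mask construction and oracles."""

import numpy as np

import woundplanim as wp


def flat_cal(pxx: float = 100.0, pxy: float = 100.0) -> wp.Calibration:
    """A calibration with no detected rule positions (grid phase 0)."""
    return wp.Calibration(px_per_cm_x=pxx, px_per_cm_y=pxy)


def wound_mask(mask: np.ndarray, pxx: float = 100.0, pxy: float = 100.0) -> wp.WoundMask:
    return wp.WoundMask(mask=np.asarray(mask, bool), cal=flat_cal(pxx, pxy))


def disk_mask(radius_cm: float, res: float, pad_px: int = 8) -> wp.WoundMask:
    """Digitized disk: pixels whose centre lies within the radius."""
    r_px = radius_cm * res
    n = int(np.ceil(2 * r_px)) + 2 * pad_px
    c = n / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    m = (ii + 0.5 - c) ** 2 + (jj + 0.5 - c) ** 2 <= r_px**2
    return wound_mask(m, res, res)


def ellipse_mask(a_cm: float, b_cm: float, res: float, pad_px: int = 8) -> wp.WoundMask:
    a_px, b_px = a_cm * res, b_cm * res
    n = int(np.ceil(2 * max(a_px, b_px))) + 2 * pad_px
    c = n / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    m = ((jj + 0.5 - c) / a_px) ** 2 + ((ii + 0.5 - c) / b_px) ** 2 <= 1.0
    return wound_mask(m, res, res)


def ring_image(
    n: int, radius_px: float, thickness_px: float, gap_px: float = 0.0
) -> np.ndarray:
    """Grayscale image of an annular stroke, optionally with an angular gap
    of the given arc length (px) centred on the +x direction."""
    c = n / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    r = np.hypot(ii + 0.5 - c, jj + 0.5 - c)
    ring = np.abs(r - radius_px) <= thickness_px / 2.0
    if gap_px > 0:
        theta = np.arctan2(ii + 0.5 - c, jj + 0.5 - c)
        half = gap_px / (2.0 * radius_px)
        ring &= ~(np.abs(theta) < half)
    return np.where(ring, 0.0, 1.0)


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Independent polygon-area oracle: signed fan triangulation from v0."""
    v = np.asarray(vertices, float)
    v0 = v[0]
    total = 0.0
    for p, q in zip(v[1:-1], v[2:]):
        d1, d2 = p - v0, q - v0
        total += 0.5 * (d1[0] * d2[1] - d1[1] * d2[0])
    return abs(total)
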