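import pytest

import woundplanim as wp


@pytest.fixture(scope="session")
def circle_trace():
    """Canonical full-sheet trace: circle of radius 3 cm (area 9*pi)."""
    return wp.render_trace(wp.make_shape("circle", radius=3.0))


@pytest.fixture(scope="session")
def circle_mask(circle_trace):
    return wp.segment(circle_trace.image)


@pytest.fixture(scope="session")
def small_grid():
    """A small ruled sheet that keeps rendering and morphology fast."""
    return wp.GridSpec(sheet_width=8.0, sheet_height=8.0)


@pytest.fixture(scope="session")
def blob_trace(small_grid):
    poly = wp.make_shape("blob", mean_radius=2.0, center=(4.3, 4.2), seed=5)
    return wp.render_trace(poly, grid=small_grid)
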