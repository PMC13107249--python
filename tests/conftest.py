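"""Shared fixtures: reduced-size geometries and phantoms for fast unit tests.

The full acquisition geometry (2000 A-lines x 1024 depth pixels x ~300
frames) is exercised by the acceptance tests; unit tests use a reduced
angular/depth sampling of the same 12.8 mm range so analytic expectations
are unchanged while frames render in milliseconds.
"""

import numpy as np
import pytest

from airwayflow.phantom import (
    AcquisitionGeometry,
    AirwayPhantom,
    RenderParams,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(alines_per_frame=256, depth_pixels=512)


@pytest.fixture(scope="session")
def quiet_render() -> RenderParams:
    """Noise-free rendering: no speckle, negligible floor, no sheath ring."""
    return RenderParams(speckle=False, floor_mean=0.001, floor_sd=0.0, sheath=False)


def straight_phantom(
    radius: float = 4.0,
    span: float = 20.0,
    offset=(0.0, 0.0),
    constriction: dict | None = None,
    windows: dict | None = None,
    seed: int = 0,
) -> AirwayPhantom:
    """Straight-tube phantom along +z with a constant radius."""
    z = np.linspace(0.0, span, max(4, int(span // 5) + 2))
    return AirwayPhantom(
        centerline_control_points=np.column_stack([np.zeros_like(z), np.zeros_like(z), z]),
        radius_stations=np.array([0.0, span]),
        radius_values=np.array([radius, radius]),
        region_windows=windows or {},
        state_constriction=constriction or {},
        offset_amplitude=offset,
        acquisition_span=span,
        seed=seed,
    )


@pytest.fixture(scope="session")
def centered_frame(small_geometry, quiet_render):
    """Noise-free frame of a centered circular lumen, r = 4 mm."""
    from airwayflow.phantom import render_bscan

    ph = straight_phantom(radius=4.0)
    return render_bscan(ph, small_geometry, 10.0, params=quiet_render)


@pytest.fixture(scope="session")
def default_pair():
    return make_phantom("awake", 0), make_phantom("asleep", 0)
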