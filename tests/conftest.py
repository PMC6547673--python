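import numpy as np
import pandas as pd
import pytest

from spheroflow import ChannelGeometry, FluidProperties, FlowContext


@pytest.fixture(scope="session")
def flow005():
    """Default chamber at the assay's optimal wall shear."""
    return FlowContext.from_shear(0.05)


@pytest.fixture(scope="session")
def plate_geometry():
    """The 1000 x 100 um cross-section used in the worked unit conversions."""
    return ChannelGeometry(width_um=1000.0, height_um=100.0)


@pytest.fixture(scope="session")
def buffer_fluid():
    return FluidProperties(viscosity_cP=0.9)


def make_track(
    xs, ys=None, frames=None, diameter=85.0, track_id=0, condition="M-CSC", field_id=0
) -> pd.DataFrame:
    """Build a trajectory table for one track from raw positions."""
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    frames = np.arange(len(xs)) if frames is None else np.asarray(frames)
    return pd.DataFrame(
        {
            "frame": frames,
            "track_id": track_id,
            "x_um": xs,
            "y_um": ys,
            "diameter_um": diameter,
            "condition": condition,
            "field_id": field_id,
        }
    )


def track_from_speeds(speeds, diameter=85.0, **kw) -> pd.DataFrame:
    """Track whose consecutive per-second speeds are exactly ``speeds``."""
    xs = np.concatenate([[0.0], np.cumsum(speeds)])
    return make_track(xs, diameter=diameter, **kw)
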