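import dataclasses

import numpy as np
import pytest

from karyosim import _kernels
from karyosim.geometry import GeometryFrame, GeometrySeries


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once so per-test timings are meaningful."""
    _kernels.warmup()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def asymmetric_frame() -> GeometryFrame:
    """Mother clearly larger than daughter, moderately narrow bridge."""
    return GeometryFrame.from_extents(
        0.0,
        mother_length=2.0,
        mother_width=1.6,
        daughter_length=1.0,
        daughter_width=0.8,
        bridge_length=1.0,
        bridge_width=0.4,
    )


@pytest.fixture
def symmetric_frame() -> GeometryFrame:
    """Mirror-identical lobes."""
    return GeometryFrame.from_extents(
        0.0,
        mother_length=1.6,
        mother_width=1.2,
        daughter_length=1.6,
        daughter_width=1.2,
        bridge_length=0.6,
        bridge_width=0.36,
    )


@pytest.fixture
def narrow_frame() -> GeometryFrame:
    """Bridge much narrower than a typical plasmid sphere."""
    return GeometryFrame.from_extents(
        0.0,
        mother_length=1.8,
        mother_width=1.4,
        daughter_length=1.2,
        daughter_width=1.0,
        bridge_length=1.2,
        bridge_width=0.08,
    )


def make_static_series(frame: GeometryFrame, duration: float, cell_id="static"):
    """Hold one frame fixed over [0, duration] (a two-frame constant series)."""
    f0 = dataclasses.replace(frame, time=0.0)
    f1 = dataclasses.replace(frame, time=duration)
    return GeometrySeries(cell_id=cell_id, frames=(f0, f1))
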