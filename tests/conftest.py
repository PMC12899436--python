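import numpy as np
import pytest

from fishstack.nucleus_registry import NucleusRecord, NucleusRegistry
from fishstack.stack_io import ZStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def square_contour(top: float, left: float, size: float) -> np.ndarray:
    """Closed square pixel polygon (row, col), counter-clockwise."""
    return np.array(
        [
            [top, left],
            [top, left + size],
            [top + size, left + size],
            [top + size, left],
            [top, left],
        ],
        dtype=float,
    )


def make_record(nucleus_id, center, contour, plane=0, area=None):
    return NucleusRecord(
        nucleus_id=nucleus_id,
        center=center,
        contour=contour,
        area_px=area if area is not None else 1.0,
        plane_index=plane,
    )


@pytest.fixture
def square_registry():
    """Registry with one 20x20 square nucleus at rows/cols 10..30."""
    registry = NucleusRegistry()
    registry.add(make_record(0, (20.0, 20.0), square_contour(10, 10, 20), area=400))
    return registry


def random_stack(rng, n_channels=3, n_planes=3, shape=(16, 16), dtype=np.uint16):
    data = rng.integers(0, 60000, size=(n_channels, n_planes, *shape)).astype(dtype)
    names = ("DAPI", "FITC", "TRITC")[:n_channels]
    return ZStack(data=data, channel_names=names)
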