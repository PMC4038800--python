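import numpy as np
import pytest

from sfxreduce.corrections import Frame
from sfxreduce.geometry import DetectorLayout, PixelMap
from sfxreduce.synth import SynthSpec, generate_stream, worked_example_frames


@pytest.fixture(scope="session")
def toy_layout() -> DetectorLayout:
    """Two 8x8 modules side by side: raw shape (8, 16)."""
    return DetectorLayout((8, 8), (1, 2))


@pytest.fixture(scope="session")
def toy_pixelmap(toy_layout) -> PixelMap:
    return PixelMap.from_layout(toy_layout, pixel_pitch=1.0)


@pytest.fixture(scope="session")
def examples():
    return worked_example_frames()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_frame(data, **kw) -> Frame:
    return Frame(data=np.asarray(data, dtype=float), **kw)


@pytest.fixture(scope="session")
def crystal_stream():
    """The default synthetic crystal run (200 frames, 20 planted hits),
    shared across tests; treat as read-only."""
    spec = SynthSpec(seed=0)
    frames, truth, cal, pm = generate_stream(spec)
    return spec, frames, truth, cal, pm
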