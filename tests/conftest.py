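import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from specklestress import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_stack(rng):
    """A small stack of i.i.d. uniform 8-bit noise frames."""
    frames = rng.integers(0, 256, size=(12, 10, 10), dtype=np.uint8)
    return FrameStack(frames=frames, fps=30.0, bit_depth=8, source_id="random")


@pytest.fixture
def static_stack(rng):
    """All frames identical (static speckle), spatially varying."""
    frame = rng.integers(1, 256, size=(8, 8), dtype=np.uint8)
    frames = np.repeat(frame[np.newaxis], 10, axis=0)
    return FrameStack(frames=frames, fps=30.0, bit_depth=8, source_id="static")


def make_stack(frames, fps=30.0, bit_depth=8, source_id="test"):
    return FrameStack(
        frames=np.asarray(frames, dtype=np.uint8 if bit_depth <= 8 else np.uint16),
        fps=fps,
        bit_depth=bit_depth,
        source_id=source_id,
    )
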