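import numpy as np
import pytest

from vidtrack import FrameStack, SpeciesSpec


def make_stack(frames, fps=25.0, scale=1.0, name="test.avi"):
    return FrameStack(
        frames=np.asarray(frames, dtype=np.uint8), fps=fps, scale=scale,
        source_name=name,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_species():
    """Three species spanning the size/speed/shape ranges the pipeline targets."""
    return [
        SpeciesSpec("alpha", major_mean=14, major_sd=1.2, aspect_mean=2.5,
                    aspect_sd=0.2, speed_mean=120, speed_sd=15, turning_sd=0.06,
                    intensity=250),
        SpeciesSpec("beta", major_mean=11, major_sd=1.0, aspect_mean=1.5,
                    aspect_sd=0.15, speed_mean=160, speed_sd=20, turning_sd=0.08,
                    intensity=190),
        SpeciesSpec("gamma", major_mean=8, major_sd=0.8, aspect_mean=1.2,
                    aspect_sd=0.1, speed_mean=110, speed_sd=12, turning_sd=0.08,
                    intensity=130),
    ]
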