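import numpy as np
import pytest

from flatbrain import phantom as ph
from flatbrain import pipeline


def _default_pattern():
    return [
        ph.PatternElement("stripe", theta=2.2, width_mm=0.25),
        ph.PatternElement("blob", theta=0.9, x_mm=1.2, width_mm=0.4, amplitude=0.8),
    ]


@pytest.fixture(scope="session")
def clean_phantom():
    """Full-scale phantom, perfectly aligned, noise-free."""
    spec = ph.PhantomSpec(pattern=_default_pattern())
    return ph.make_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def clean_recon(clean_phantom):
    return pipeline.reconstruct(clean_phantom.project, clean_phantom.images)


@pytest.fixture(scope="session")
def clean_flatmap(clean_recon):
    return pipeline.flatten_layer(clean_recon, "L4")


@pytest.fixture(scope="session")
def misaligned_phantom():
    """Full-scale phantom with rigid misalignments up to 10 deg / 20 px."""
    spec = ph.PhantomSpec(
        pattern=_default_pattern(), max_rotation_deg=10.0, max_jitter_px=20.0
    )
    return ph.make_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled phantom for unit tests that only need structure."""
    spec = ph.PhantomSpec(
        n_slices=8, n_bins=60, radius_mm=1.5,
        pattern=[ph.PatternElement("stripe", theta=1.8, width_mm=0.3)],
    )
    return ph.make_phantom(spec, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
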