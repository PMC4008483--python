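import numpy as np
import pytest

from pcplan.phantom import PhantomSpec, generate_phantom, generate_profile_population
from pcplan.planning import build_template
from pcplan.segmentation import adaptive_artery_threshold, otsu_body_mask


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(seed=7, noise_sd=0.0, tissue_sd=10.0)


@pytest.fixture(scope="session")
def phantom_default(default_spec):
    """Default (noisy) phantom volume with its ground truth."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def phantom_noiseless(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def seg_default(phantom_default):
    volume, _ = phantom_default
    body = otsu_body_mask(volume)
    return adaptive_artery_threshold(volume, body)


@pytest.fixture(scope="session")
def templates(default_spec):
    """Left/right VA templates averaged from ten jittered phantom profiles."""
    out = {}
    for i, side in enumerate(("L", "R")):
        pop = generate_profile_population(10, default_spec, side=side, seed=100 + i)
        out[side] = build_template(pop, pad=10, side=side)
    return out
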