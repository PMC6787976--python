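import dataclasses

import numpy as np
import pytest

from lobarflow import PhantomSpec, generate_phantom_pair


def small_spec(**overrides) -> PhantomSpec:
    """A fast, small-grid phantom spec with the default healthy mixture.

    Volumes are scaled to fit a 48³ grid at 2 mm spacing while keeping the
    default flow split exact.
    """
    scale = 0.055
    base = PhantomSpec()
    defaults = dict(
        grid_shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        expanded_volumes_l={k: v * scale for k, v in base.expanded_volumes_l.items()},
        contracted_volumes_l={k: v * scale for k, v in base.contracted_volumes_l.items()},
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """One small healthy phantom pair with ground truth (shared, read-only)."""
    return generate_phantom_pair(small_spec(seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    """A full-size (128³) healthy phantom pair at the default study volumes."""
    return generate_phantom_pair(PhantomSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
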