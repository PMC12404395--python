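import numpy as np
import pytest

from aneumorph import ShapeSpec, make_mesh


@pytest.fixture(scope="session")
def icosphere_r2():
    """Icosphere radius 2 mm, subdivision 4, with its closed-form oracle."""
    return make_mesh(ShapeSpec(kind="icosphere", radius=2.0, subdivisions=4))


@pytest.fixture(scope="session")
def hemisphere_cylinder():
    """Hemispherical sac (r = 2 mm) + parent tube (r = 1.5 mm)."""
    return make_mesh(
        ShapeSpec(kind="hemisphere-on-cylinder", radius=2.0, parent_radius=1.5,
                  subdivisions=6)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
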