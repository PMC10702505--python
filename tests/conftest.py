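"""Shared phantom fixtures.

The expensive volumes (rasterization + centerline extraction) are built
once per session; tests must treat them as read-only.
"""

import numpy as np
import pytest

from cwpqct import (
    cylinder_phantom,
    default_phantom_spec,
    generate_volume,
    label_branches,
    skeletonize,
    y_phantom,
)


@pytest.fixture(scope="session")
def cylinder_volume():
    """Straight airway tube: r_in 4 mm, wall 1 mm, 40 mm, 0.5 mm voxels."""
    return generate_volume(cylinder_phantom(r_in=4.0, wall=1.0, length=40.0,
                                            spacing=0.5, noise_sd=0.0))


@pytest.fixture(scope="session")
def cylinder_tree(cylinder_volume):
    return skeletonize(cylinder_volume)


@pytest.fixture(scope="session")
def y70_volume():
    """Bifurcation phantom with a 70-degree included angle, 0.5 mm voxels."""
    return generate_volume(y_phantom(70.0, spacing=0.5))


@pytest.fixture(scope="session")
def y70_tree(y70_volume):
    return skeletonize(y70_volume)


@pytest.fixture(scope="session")
def full_phantom():
    """The 26-branch bronchial tree at 0.75 mm isotropic, noise-free."""
    vol = generate_volume(default_phantom_spec(noise_sd=0.0))
    tree = label_branches(skeletonize(vol))
    return vol, tree


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
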