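import numpy as np
import pytest

from ffasr.imaging import PatchPairSet


def make_patch_set(x_l, x_h, factor=2):
    """Wrap raw matrices in a PatchPairSet (positions/means are placeholders)."""
    n = x_l.shape[1]
    return PatchPairSet(
        X_l=np.asarray(x_l, float),
        X_h=np.asarray(x_h, float),
        positions=np.zeros((n, 2), dtype=np.intp),
        lr_means=np.zeros(n),
        factor=factor,
    )


@pytest.fixture(scope="session")
def linear_map_patches():
    """Planted fixture: HR patches are one fixed linear map of the LR patches."""
    rng = np.random.default_rng(42)
    a = rng.normal(size=(36, 9))
    x_l = rng.normal(size=(9, 400))
    return make_patch_set(x_l, a @ x_l), a


@pytest.fixture(scope="session")
def small_dataset():
    """3 groups x 4 images at 96^2, factor 2 — shared across pipeline tests."""
    from ffasr.phantom import generate_grouped_dataset

    return generate_grouped_dataset(n_groups=3, per_group=4, factor=2, image_size=96, seed=7)
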