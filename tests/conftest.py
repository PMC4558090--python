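import numpy as np
import pytest

import mammodense as md


@pytest.fixture(scope="session")
def small_params():
    """Reduced frame for fast field-level tests (same texture-to-cell ratio
    as the default generator)."""
    return md.SyntheticParams(image_height_px=144, image_width_px=108,
                              corr_length=8.0, noise_sd=5.0, seed=0)


@pytest.fixture(scope="session")
def small_truth(small_params):
    mask = md.generate_breast_mask(small_params)
    return md.generate_density_field(mask, 40.0, small_params.corr_length,
                                     small_params.anterior_weight, seed=1)


@pytest.fixture(scope="session")
def small_image(small_params, small_truth):
    return md.render_mammogram(small_truth, small_params, seed=2)


@pytest.fixture(scope="session")
def default_weights():
    return md.build_weight_matrix(8, 6)


def rect_mask(h, w, full=True, seed=None):
    """Simple rectangular or random-blob mask helper."""
    if full:
        return np.ones((h, w), dtype=bool)
    rng = np.random.default_rng(seed)
    m = np.zeros((h, w), dtype=bool)
    r, c = rng.integers(0, h), rng.integers(0, w)
    m[max(0, r - h // 3):r + h // 3 + 1, max(0, c - w // 3):c + w // 3 + 1] = True
    return m
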