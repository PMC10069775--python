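import numpy as np
import pytest

from haircell import synthetic


@pytest.fixture(scope="session")
def default_cochlea():
    """One default-condition synthetic cochlea shared across tests."""
    return synthetic.render(seed=7)


@pytest.fixture(scope="session")
def analyzed_cochlea(default_cochlea):
    """The default cochlea pushed through the full pipeline."""
    from haircell.outputs import AnalysisConfig, analyze_image

    cfg = AnalysisConfig(pixel_size_nm=default_cochlea.image.pixel_size_nm, seed=7)
    return analyze_image(default_cochlea.image, cfg)


def make_blob_tile(cells, size=64, noise_sd=0.0, seed=0):
    """Render a small two-channel tile from (row, col, label) specs.

    Blob sigmas/amplitudes mirror the synthetic generator's class profiles
    at the default working pixel size (1.152 um/px).
    """
    um_per_px = synthetic.DEFAULT_PIXEL_SIZE_NM / 1000.0
    soma = np.zeros((size, size))
    bundle = np.zeros((size, size))
    for row, col, label in cells:
        synthetic._add_blob(
            soma, row, col, synthetic.DEFAULT_SOMA_SIGMA_UM[label] / um_per_px,
            synthetic.DEFAULT_SOMA_AMPLITUDE[label],
        )
        synthetic._add_blob(
            bundle, row, col, synthetic.DEFAULT_BUNDLE_SIGMA_UM[label] / um_per_px,
            synthetic.DEFAULT_BUNDLE_AMPLITUDE[label],
        )
    if noise_sd:
        rng = np.random.default_rng(seed)
        soma = soma + rng.normal(0, noise_sd, soma.shape)
        bundle = bundle + rng.normal(0, noise_sd, bundle.shape)
    return np.clip(np.stack([soma, bundle]), 0.0, 1.0)
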