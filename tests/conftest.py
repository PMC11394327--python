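import numpy as np
import pytest

import dermahair as dh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_image():
    """The 2x2 single-channel worked example image."""
    return dh.RasterImage(np.array([[0.3, 0.6], [0.5, 0.8]]))


@pytest.fixture
def toy_mask():
    return dh.HairMask(np.array([[1, 0], [0, 1]]))


def make_pairs(seed: int, n: int, size: int = 16, n_lines: int = 6):
    """Procedural paired samples: lesion textures degraded by line synthesis."""
    pairs = []
    for i in range(n):
        clean = dh.make_lesion_texture(seed * 1000 + i, (size, size))
        hairy = dh.synth_line_hair(clean, n_lines=n_lines, seed=seed * 2000 + i)
        pairs.append(dh.PairedSample(hairy=hairy, clean=clean,
                                     label=dh.CLASSES[i % 7], id=f"s{i:03d}"))
    return pairs


@pytest.fixture
def tiny_denoiser_config():
    return dh.DenoiserConfig(image_channels=1, base_channels=8,
                             depth_multipliers=(1, 2), n_res_blocks=1,
                             time_embed_dim=8)
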