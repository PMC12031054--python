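import numpy as np
import pandas as pd
import pytest

from leafspad.color_features import feature_table
from leafspad.imaging import MeanChannelColor
from leafspad.synthetic_data import SyntheticConfig, generate_dataset, sample_spad


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """40 small leaves, light noise: fast but realistic test images."""
    return SyntheticConfig(n_samples=40, image_size=(96, 96), pixel_noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_cfg):
    """On-disk synthetic dataset shared by the pipeline tests."""
    root = tmp_path_factory.mktemp("leafset")
    manifest = generate_dataset(small_cfg, root)
    return root, manifest


@pytest.fixture(scope="session")
def color_table() -> pd.DataFrame:
    """Feature table built from the generator's analytic SPAD→color law
    (no rendering), n=200: the fast stand-in for a segmented dataset."""
    cfg = SyntheticConfig(seed=5)
    rng = np.random.default_rng(5)
    spad = sample_spad(cfg, 200, seed=50)
    colors = []
    for s in spad:
        r, g, b = cfg.leaf_mean_rgb(float(s))
        jit = rng.normal(0, 0.3, 3)  # residual color noise after pixel averaging
        colors.append(MeanChannelColor(r + jit[0], g + jit[1], b + jit[2], 1000))
    return feature_table(colors, spad.tolist())
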