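import numpy as np
import pytest

from mcmf.channels import ChannelConfig
from mcmf.pipeline import PipelineConfig
from mcmf.preprocess import compute_fov_mask, enhance
from mcmf.superpixels import SlicParams
from mcmf.synthetic import PhantomSpec, generate_synthetic_fundus


@pytest.fixture(scope="session")
def phantom():
    """One 384x384 phantom with lesions, shared across the session."""
    spec = PhantomSpec(size=(384, 384), seed=11)
    return generate_synthetic_fundus(spec)


@pytest.fixture(scope="session")
def phantom_noiseless():
    spec = PhantomSpec(size=(384, 384), seed=12, noise_sigma=0.0)
    return generate_synthetic_fundus(spec)


@pytest.fixture(scope="session")
def phantom_pre(phantom):
    """Preprocessing products of the shared phantom."""
    img, truth = phantom
    fov = compute_fov_mask(img)
    pre = enhance(img, fov)
    return img, truth, fov, pre


@pytest.fixture(scope="session")
def desk_config():
    """Pipeline configuration for desk-scale (384 px) phantoms."""
    return PipelineConfig(
        slic=SlicParams(region_size=16, min_region_fraction=0.1),
        channels=ChannelConfig(scale_to_width=True),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
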