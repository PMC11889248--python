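import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_image_pool(tmp_path_factory):
    """A tiny on-disk synthetic pool (48 images, balanced) shared by
    pipeline/evaluation tests."""
    from mnvit.synthetic import easy_spec, generate_dataset

    out = tmp_path_factory.mktemp("pool")
    samples, manifest = generate_dataset(48, 0.5, easy_spec(32), seed=7, out_dir=out)
    return samples, manifest
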