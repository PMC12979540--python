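import numpy as np
import pytest

from lmppm.architectures import OMNetConfig, build_omnet
from lmppm.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small 3-class synthetic image folder shared across tests."""
    out = tmp_path_factory.mktemp("tinydata")
    spec = SyntheticSpec(n_classes=3, images_per_class=10, image_size=32,
                         seed=11)
    manifest = generate_dataset(spec, out)
    return out, spec, manifest


@pytest.fixture()
def micro_config():
    """The smallest config that exercises every block kind."""
    return OMNetConfig(stem_channels=8, stage_widths=(8, 8, 16, 16),
                       residual_repeats=(1, 0, 1, 0), head_channels=16,
                       pool_output=1, num_classes=3, input_size=32)


@pytest.fixture()
def micro_graph(micro_config):
    return build_omnet(micro_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
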