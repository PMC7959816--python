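import pytest

from svconfide.config import PipelineConfig
from svconfide.synth import make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle: 3 x 500 kb chromosomes, ~107 truth
    SVs + 6 labeled decoys, 60 outbred samples in 3 populations + 4 DH
    lines, noiseless depth."""
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()
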