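import pytest

from chunklearn import RunConfig, memory_from_symbols

# the six-symbol toy whose only bigram uncertainty follows b
TOY = "abdabe"
# the segmentation toy with the thrice-repeated "ee"
FIG_TOY = "beeceedee"


@pytest.fixture
def toy_ids():
    return list(TOY)


@pytest.fixture
def fig_ids():
    return list(FIG_TOY)


@pytest.fixture
def toy_memory():
    """The six-symbol toy with indicator-vector geometry so merges can be
    licensed."""
    return memory_from_symbols(TOY, RunConfig(space_mode="indicator"))
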