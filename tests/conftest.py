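import numpy as np
import pytest

from coexthresh import generate_block_dataset


@pytest.fixture(scope="session")
def block_data():
    """The default 20-gene two-block dataset with its real-valued truth."""
    return generate_block_dataset()


@pytest.fixture(scope="session")
def block_truth_binary():
    """Binarized ground truth of the default block design."""
    _, truth = generate_block_dataset(binarize=True)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
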