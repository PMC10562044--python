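import numpy as np
import pytest

from lu177planar import experiments as ex


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_model():
    """One seed-fixed desk-scale training shared by the expensive
    experiments: 30 synthetic 96x96 scenes, reduced network profile,
    2000 Adam iterations."""
    model, history, dataset = ex.train_desk_model(seed=0)
    return {"model": model, "history": history, "dataset": dataset}
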