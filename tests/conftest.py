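import numpy as np
import pytest

import fermsurro as fs


@pytest.fixture(scope="session")
def table1():
    """The packaged 15-run experiment as a Dataset (Y1 on fraction scale)."""
    return fs.Dataset.from_frame(fs.load_table1())


@pytest.fixture(scope="session")
def factors():
    return fs.load_factors()


@pytest.fixture(scope="session")
def factor_bounds(factors):
    return [(f.minimum, f.maximum) for f in factors]


@pytest.fixture(scope="session")
def model_y1():
    return fs.published_model("Y1")


@pytest.fixture(scope="session")
def model_y2():
    return fs.published_model("Y2")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
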