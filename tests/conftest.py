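import numpy as np
import pytest

from afribee import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def measurement_table(tmp_path):
    """A small well-formed CSV measurement table."""
    path = tmp_path / "measurements.csv"
    path.write_text(
        "specimen_id,site_id,FWL,HWL,TL,FL,habitat\n"
        "bee1,siteA,9.0,6.0,3.2,2.6,scrub\n"
        "bee2,siteA,9.1,6.1,3.3,2.7,scrub\n"
    )
    return path
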