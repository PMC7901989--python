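import numpy as np
import pytest

from ferracet import generate_culture, preset
from ferracet.culture import CultureSeries


@pytest.fixture(scope="session")
def gt1_organo_noiseless():
    return generate_culture(preset("gt1-organo"))


@pytest.fixture(scope="session")
def gt1_litho_noiseless():
    return generate_culture(preset("gt1-litho"))


@pytest.fixture
def simple_series():
    """Hand-built series: exponential growth, linear Fe(II) rise."""
    t = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    return CultureSeries(
        species="testsp",
        condition="organotrophic",
        mineral="HFO",
        replicate_id="1",
        time_days=t,
        acetate_mM=3.0 * t,
        fe2_total_mM=0.5 * t,
        cell_density=1e6 * np.exp(0.6 * t),
        ethanol_mM=20.0 - 2.0 * t,
        fe2_soluble_mM=0.4 * t,
        fe3_initial_mM=9.0,
    )
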