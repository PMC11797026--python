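import numpy as np
import pytest

from crossplan import make_fixture_config
from crossplan.config import CrossSystemSpec


@pytest.fixture
def core_tiny():
    return make_fixture_config("core_tiny", seed=1)


@pytest.fixture
def whole_3way():
    return make_fixture_config("whole_3way", seed=1)


@pytest.fixture
def opt_toy():
    return make_fixture_config("opt_toy", seed=1)


@pytest.fixture
def system_3way():
    """Classic fully-multiplied 3-way system, small lifetimes."""
    return CrossSystemSpec(
        n_way=3,
        breeds=["A", "B", "C"],
        multiplier_flags={"A": True, "B": True, "C": True},
        tier_lifetimes={"M_A": 2, "M_B": 2, "M_C": 2, "H_AB": 2,
                        "N_A": 2, "N_B": 2, "N_C": 2},
        tier_litter_sizes={"H_AB": 8, "H_ABC": 8},
        n_seasons=6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
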