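import numpy as np
import pytest

from pollenlag import SimulationParams, simulate_survey
from pollenlag.ordinal import ClmSpec, Design


@pytest.fixture(scope="session")
def small_survey():
    """Three sites, one year, 8 trees: quick to fit, clear site signal."""
    params = SimulationParams(
        sites=(("AC", 0.0), ("RM", 5.0), ("BE", 12.0)),
        years=((2014, 0.0),),
        n_trees=8,
        tree_sd=2.0,
        seed=42,
    )
    return simulate_survey(params)


@pytest.fixture(scope="session")
def multi_year_survey():
    """Paper-style coverage: 5 sites, 3 years, two sites missing year one."""
    params = SimulationParams(
        n_trees=10,
        site_years={"BL": [2015, 2016], "LD": [2015, 2016]},
        seed=7,
    )
    return simulate_survey(params)


def make_design(y_codes, X, n_levels):
    """Bare design for likelihood-level tests."""
    y = np.asarray(y_codes, dtype=np.int64)
    X = np.asarray(X, dtype=float)
    return Design(y=y, X=X, xnames=[f"x{j}" for j in range(X.shape[1])],
                  levels={}, response_levels=list(range(1, n_levels + 1)),
                  spec=ClmSpec(time_term=None, factors=()))
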