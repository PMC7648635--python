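import numpy as np
import pandas as pd
import pytest

from herbpersist.community import (DEFAULT_TRAIT_SCHEMA, SurveySeries,
                                   TraitTable)

# The seven worked occupancy patterns used to illustrate the WRT index,
# with their mean relative covers and the index values that are internally
# consistent with the formula (two printed cells are not; see the module
# docs).  Layout: pattern, relcov, wrt_pa, wrt_abu (None = inconsistent).
WORKED_EXAMPLES = [
    ("sp_1", (1, 0, 1, 0, 1, 0, 1, 0), 0.5, 12.5, 6.25),
    ("sp_2", (1, 1, 0, 0, 0, 0, 0, 0), 0.6, 25.0, 15.0),
    ("sp_3", (0, 0, 1, 1, 0, 0, 1, 0), 0.3, None, None),
    ("sp_4", (0, 0, 1, 1, 1, 0, 1, 0), 0.4, 25.0, 10.0),
    ("sp_5", (1, 1, 1, 1, 1, 1, 1, 1), 0.7, 100.0, 70.0),
    ("sp_6", (1, 1, 1, 1, 1, 1, 1, 0), 0.8, 87.5, 70.0),
    ("sp_7", (1, 1, 1, 0, 1, 1, 0, 0), 0.5, 31.25, None),
]


def worked_example_series() -> SurveySeries:
    """One unit per worked pattern, with a filler species tuned so that the
    focal species' mean relative cover equals the printed Rel.cov."""
    surveys = [1999, 2000, 2001, 2002, 2005, 2006, 2008, 2011]
    units = [name for name, *_ in WORKED_EXAMPLES]
    species = [f"focal_{name}" for name, *_ in WORKED_EXAMPLES] + ["filler"]
    cover = np.zeros((len(units), len(species), 8))
    for iu, (name, patt, relcov, *_t) in enumerate(WORKED_EXAMPLES):
        focal = 10.0 * relcov
        cover[iu, iu, :] = [focal if p else 0.0 for p in patt]
        # filler tops the unit total up to 10 wherever the focal is present
        cover[iu, -1, :] = [10.0 - focal if p else 5.0 for p in patt]
    return SurveySeries("worked", surveys, units, species, cover)


@pytest.fixture
def table_series() -> SurveySeries:
    return worked_example_series()


@pytest.fixture
def toy_traits() -> TraitTable:
    df = pd.DataFrame({
        "seed_mass": [1.2, 6.0, 30.0, 0.4],
        "bud_bank": [True, False, True, False],
        "sla": [25.0, 12.0, 18.0, 31.0],
        "vegetative_mobility": ["fast", "none", "slow", "fast"],
        "leaf_anatomy": ["mesomorphic", "scleromorphic", "helomorphic",
                         "hygromorphic"],
    }, index=pd.Index(["sp_a", "sp_b", "sp_c", "sp_d"], name="species"))
    return TraitTable(DEFAULT_TRAIT_SCHEMA, df)
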