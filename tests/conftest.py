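import numpy as np
import pytest

from mrpop.core_data import Component, DimensionRegistry
from mrpop.synthetic import GeneratorConfig, make_full_fixture


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """3-region, full-age synthetic system at reduced exposure scale."""
    return GeneratorConfig(
        n_regions=3,
        n_ages=18,
        vital_years=tuple(range(1991, 2012)),
        migration_years=(1996, 2001, 2006, 2011),
        exposure_scale=0.02,
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    rng = np.random.default_rng(42)
    return make_full_fixture(small_cfg, rng)


@pytest.fixture
def tiny_registry() -> DimensionRegistry:
    """Two regions, four age groups, annual years: the smallest useful system."""
    return DimensionRegistry(
        regions=("A", "B"),
        age_groups=(0, 5, 10, 15),
        years=(2000, 2001, 2002),
        reproductive_window=(2, 3),
    )


@pytest.fixture
def full_age_registry() -> DimensionRegistry:
    return DimensionRegistry(
        regions=("A", "B", "C"),
        age_groups=tuple(5 * i for i in range(18)),
        years=(2011,),
        reproductive_window=(3, 9),
    )
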