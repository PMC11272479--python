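"""Shared fixtures: small synthetic limbs and cohorts.

Geometric tests use a reduced mesh resolution (96 x 64, above the
generator's guaranteed-recovery minimum) to keep the suite fast; the
acceptance tests use the generator defaults.
"""

import numpy as np
import pytest

from rectimap.synthetic import (
    CohortStructure,
    SyntheticLimbSpec,
    generate_cohort_table,
    generate_limb,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticLimbSpec(n_theta=96, n_axial=64)


@pytest.fixture(scope="session")
def limb_bundle(small_spec):
    """(limb, landmarks, masks) at test resolution."""
    return generate_limb(small_spec)


@pytest.fixture(scope="session")
def default_limb_bundle():
    """(limb, landmarks, masks) at the generator's default resolution."""
    return generate_limb(SyntheticLimbSpec())


@pytest.fixture(scope="session")
def cohort_163():
    return generate_cohort_table(163, CohortStructure(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
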