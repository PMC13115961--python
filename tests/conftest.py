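from __future__ import annotations

import numpy as np
import pytest

import mirsa as M
from mirsa.features import DiscriminantFeature, DiscriminantFeatureSet
from mirsa.synthetic import compact_spec

TRUE_TUMOR_FEATURES = DiscriminantFeatureSet("tumor", [
    DiscriminantFeature(1082.0, "ppf", 0.0, 0.0),
    DiscriminantFeature(1362.0, "npf", 0.0, 0.0),
])


@pytest.fixture(scope="session")
def sample():
    """One heterogeneous compact synthetic sample (raw cube)."""
    return M.generate_sample(compact_spec(seed=1), 0)


@pytest.fixture(scope="session")
def preprocessed(sample):
    cube, valid = M.preprocess(sample.cube, mask=sample.mask)
    return cube, valid


@pytest.fixture(scope="session")
def cohort_projections():
    """Projections of a 7-sample compact cohort using the planted bands.

    The last sample is the homogeneous (non-tumor) control.
    """
    spec = compact_spec(seed=11, n_samples=7)
    cohort = M.generate_cohort(spec)
    projs = []
    for s in cohort:
        pc, valid = M.preprocess(s.cube, mask=s.mask)
        projs.append(M.project(pc, TRUE_TUMOR_FEATURES, valid))
    return cohort, projs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
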