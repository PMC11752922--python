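import warnings

import numpy as np
import pandas as pd
import pytest

from losformer import synth
from losformer.schema import Cohort, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def _toy_frame(n=5, seed=0):
    """Small schema-valid table with hand-controllable targets."""
    rng = np.random.default_rng(seed)
    sch = default_schema()
    cols = {}
    for e in sch.feature_entries:
        if e.kind == "binary":
            cols[e.name] = rng.integers(0, 2, size=n).astype(float)
        elif e.kind == "integer":
            cols[e.name] = rng.integers(3, 16, size=n).astype(float)
        else:
            cols[e.name] = np.round(rng.uniform(1, 100, size=n), 3)
    cols["ICU_LOS"] = np.round(rng.uniform(1, 16, size=n), 3)
    return pd.DataFrame(cols)


@pytest.fixture
def toy_frame():
    return _toy_frame()


@pytest.fixture
def toy_cohort(schema):
    return Cohort(schema, _toy_frame(n=40, seed=1))


@pytest.fixture(scope="session")
def calibrated_marginals():
    """Table-calibrated marginals, shared across the suite (MC check at a
    reduced size; the acceptance tests recalibrate at full size)."""
    marg, _ = synth.published_cohort_specs()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.calibrate_all_marginals(marg, n_mc=50_000, seed=0)


@pytest.fixture(scope="session")
def calibrated_copula(calibrated_marginals):
    _, cop = synth.published_cohort_specs()
    return synth.calibrate_latent(cop, calibrated_marginals, n_mc=50_000, seed=3)


@pytest.fixture(scope="session")
def mechanism():
    return synth.MechanismSpec(
        additive_weights={"GCS": -1.2, "PF": -0.8, "lactate": 0.6},
        interaction_terms=[(("GCS", "MV"), 0.8), (("PF", "VASO"), -0.5)],
        noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def mechanistic_cohort(calibrated_marginals, mechanism):
    return synth.generate_mechanistic(2000, 11, mechanism, calibrated_marginals)
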