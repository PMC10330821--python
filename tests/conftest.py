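import numpy as np
import pytest

import granchan as gc


@pytest.fixture(scope="session")
def default_em_report():
    """Full-scale immuno-EM pipeline run at the generator defaults (seed 1).

    Expensive (324 granules across 3 fields); shared by the acceptance tests.
    """
    data = gc.make_em_dataset(gc.EMFieldParams(seed=1), n_fields=3)
    report = gc.run_em_pipeline([(img, rings) for img, rings, _ in data], seed=1)
    truth = data[0][2]
    return report, data


@pytest.fixture()
def sparse_noiseless_field():
    """Low-density, noise-free field for truth-recovery checks."""
    params = gc.EMFieldParams(n_granules=24, chgb_count_rate=2.0,
                              insulin_count_rate=3.0, noise_sd=0.0,
                              label_gap_nm=2.0, seed=11)
    return gc.make_em_field(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
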