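"""Shared fixtures: a shortened synthetic study kept small for test speed.

The short scenario uses the minimum legal biomass-production phase
(21 h) and an 8 h production phase; everything else matches the default
study conditions.
"""

import pytest

from phesense import cgm, pipeline, synthetic

SHORT = dict(phase2_hours=21.0, phase3_hours=8.0)


@pytest.fixture(scope="session")
def params():
    return cgm.CGMParameters()


@pytest.fixture(scope="session")
def short_ref():
    """Shortened reference process (high-IPTG), seed 7."""
    return synthetic.make_scenario("reference_high_iptg", seed=7, **SHORT)


@pytest.fixture(scope="session")
def short_models(short_ref):
    """Phase-wise PLS models trained on the shortened reference process."""
    models, reports, train_rmse = pipeline.cmd_train(short_ref, pipeline.RunConfig(seed=7))
    return models


@pytest.fixture(scope="session")
def x0_arr():
    return cgm.CGMState().to_array()


@pytest.fixture(scope="session")
def default_P0(x0_arr):
    return pipeline.default_P0(x0_arr)
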