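"""Shared fixtures.

The expensive fixture is ``desk_study``: one scaled-down end-to-end
training run (40 phantom patients, both networks) shared by every test
that needs trained weights. Everything else is generated per-test at small
problem sizes.
"""

import numpy as np
import pytest

from catseg import workflows
from catseg.blocks import NetworkConfig
from catseg.phantom import generate_cohort, make_phantom_spec, render_patient


@pytest.fixture(scope="session")
def desk_study():
    """Train the full cascade on a 40-patient phantom cohort (desk scale)
    and evaluate it on the held-out patients. Shared across the session."""
    config = workflows.desk_study_config(seed=7, n_patients=40)
    result = workflows.train_study(config)
    cascade_report, whole_report = workflows.evaluate_cascade(result, config)
    return {
        "config": config,
        "result": result,
        "cascade": cascade_report,
        "whole": whole_report,
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six small-grid phantom patients for fast structural tests."""
    return generate_cohort(6, seed=11, grid_shape=(48, 48, 6),
                           spacing=(5.0, 5.0, 8.0), n_distractors=2)


@pytest.fixture()
def nor_patient():
    spec = make_phantom_spec("NOR", seed=5)
    return render_patient(spec, "patient001")


@pytest.fixture()
def tiny_net_config():
    """A minimal valid network configuration for fast forward passes."""
    return NetworkConfig(
        atrous_rates=(1, 2, 3),
        fire_specs=tuple([(2, 4, 4)] * 9),
        aspp_out_channels=8, depth=2, base_channels=4,
        stem_channels=4, decoder_channels=8, low_level_channels=4, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
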