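"""Session-scoped protocol runs shared by the protocol and acceptance tests.

Every fixture runs in the desk-scale profile with a fixed seed; the heavy
steps (generic pretraining, one run per protocol) execute once per session
and their results are analysed by several tests.
"""

import pytest

from slowplace.protocols import (
    pretrain_base,
    run_cue_rotation,
    run_linear_track,
    run_rhombus,
    run_stretch,
)
from slowplace.workbench import SCALED_PROFILE

SEED = 1


@pytest.fixture(scope="session")
def profile():
    return SCALED_PROFILE


@pytest.fixture(scope="session")
def base_net(profile):
    return pretrain_base(profile, seed=SEED)


@pytest.fixture(scope="session")
def linear_result(profile, base_net):
    return run_linear_track(profile, seed=SEED, base=base_net)


@pytest.fixture(scope="session")
def rhombus_result(profile, base_net):
    return run_rhombus(profile, seed=SEED, base=base_net)


@pytest.fixture(scope="session")
def cue_result(profile, base_net):
    return run_cue_rotation(profile, seed=SEED, base=base_net)


@pytest.fixture(scope="session")
def stretch_result(profile, base_net):
    return run_stretch(profile, seed=SEED, base=base_net, variants=((120, 60),))
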