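import numpy as np
import pytest

from probekit import DoseRespParams, gen_nanodroplet

#: Published fit of the benzimidazole probe's pH titration (canonical
#: orientation: A1 = high-pH asymptote, p < 0).
TABLE1 = DoseRespParams(a1=0.0052, a2=1.08597, log_x0=2.86045, p=-1.61012)


@pytest.fixture(scope="session")
def table1_params() -> DoseRespParams:
    return TABLE1


@pytest.fixture(scope="session")
def small_droplet():
    """A small seeded water nanodroplet shared across SDF tests."""
    return gen_nanodroplet(n_frames=4, n_solvent=20, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
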