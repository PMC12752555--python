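import numpy as np
import pytest

from mtfold import (ElasticityParams, ForceProtocol, SimulationConfig,
                    default_construct)


@pytest.fixture(scope="session")
def elasticity():
    return ElasticityParams()


@pytest.fixture(scope="session")
def le_model():
    return default_construct("LE-CSP-GS")


@pytest.fixture(scope="session")
def all_models():
    return {cid: default_construct(cid)
            for cid in ("LE-CSP-GS", "KL-CSP-GS", "KL-CSP-LE")}


@pytest.fixture
def constant_config(le_model):
    def make(force=5.5, duration=500.0, seed=1, **kw):
        return SimulationConfig(
            construct=kw.pop("construct", le_model),
            protocol=ForceProtocol(kind="constant", constant_force=force),
            duration=duration, seed=seed, **kw)

    return make


@pytest.fixture
def ramp_config(le_model):
    def make(seed=1, start=2.0, end=42.0, rate=1.0, round_trip=True, **kw):
        return SimulationConfig(
            construct=kw.pop("construct", le_model),
            protocol=ForceProtocol(kind="ramp", ramp_start=start,
                                   ramp_end=end, ramp_rate=rate,
                                   round_trip=round_trip),
            seed=seed, **kw)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
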