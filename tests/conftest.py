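import numpy as np
import pytest

import olivonet as ov
from olivonet import config as cfgmod


@pytest.fixture(scope="session")
def toy_net():
    """Small (2%-scale) scaffold shared by fast structural/dynamics tests."""
    return cfgmod.make_toy_network(0.02, seed=0)


@pytest.fixture(scope="session")
def full_net():
    """The default full-scale scaffold (built once per session)."""
    return ov.build_network(placement_seed=0, connectivity_seed=1)


@pytest.fixture(scope="session")
def full_report(full_net):
    return ov.connectivity_report(full_net)


@pytest.fixture(scope="session")
def paired_runs(full_net):
    """Matched EGLIF/LIF simulations (n = 5 each) on the session scaffold.

    Shared by the network-dynamics and headline-statistics tests so the
    ten full simulations run only once.
    """
    cfg = cfgmod.default_config()
    out = {"cfg": cfg, "records": {}, "analysis": {}}
    for model in ("EGLIF", "LIF"):
        recs, anas = [], []
        for k in range(5):
            rec = cfgmod.simulate_from_config(cfg, full_net, run_index=k,
                                              model=model)
            recs.append(rec)
            anas.append(cfgmod.analyze_run(cfg, full_net, rec))
        out["records"][model] = recs
        out["analysis"][model] = anas
    return out
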