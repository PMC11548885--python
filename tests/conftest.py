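import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mvbtrial as mvb

# reproducible hypothesis runs, no on-disk example database
settings.register_profile(
    "ci", derandomize=True, database=None, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def es3_binary_fit():
    """A moderate multivariate fit on heterogeneous synthetic data, shared
    across tests that only need *some* fitted posterior."""
    dgm = mvb.preset("ES3", covariate="binary", rho=0.2, n_per_arm=500, seed=7)
    data, manifest = mvb.generate(dgm)
    spec = dgm.model_spec()
    design = mvb.build_design(data, spec)
    H = mvb.config_matrix(spec.K)
    c = mvb.encode_responses(data[list(spec.outcomes)].to_numpy(), H)
    sample = mvb.fit_mlr(design, c, H,
                         settings=mvb.GibbsSettings(iterations=600, burnin=200,
                                                    chains=2, seed=123))
    return {"dgm": dgm, "data": data, "manifest": manifest, "sample": sample,
            "spec": spec, "H": H}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240511)
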