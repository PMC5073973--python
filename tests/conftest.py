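import numpy as np
import pytest

from ccpromise.core_data import EndpointSpec, EndpointTable, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(20240915))


@pytest.fixture
def small_dataset(rng):
    """12-sample, 3+2-feature two-omics dataset with 2 quantitative endpoints."""
    n = 12
    samples = [f"s{i}" for i in range(n)]
    meth = OmicsMatrix([f"cg{j}" for j in range(3)], samples, rng.standard_normal((3, n)))
    expr = OmicsMatrix([f"ps{j}" for j in range(2)], samples, rng.standard_normal((2, n)))
    specs = [
        EndpointSpec("ep1", "quantitative", 1),
        EndpointSpec("ep2", "quantitative", -1),
    ]
    endpoints = EndpointTable(
        samples, specs, {"ep1": rng.standard_normal(n), "ep2": rng.standard_normal(n)}
    )
    return meth, expr, endpoints
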