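import numpy as np
import pytest

from sisnet import (EpidemicParams, Network, generate_k_regular,
                    quasi_stationary_prevalence)


@pytest.fixture(scope="session")
def params11():
    return EpidemicParams(tau=1.0, gamma=1.0)


@pytest.fixture(scope="session")
def ring8():
    return Network.from_edges(8, [(i, (i + 1) % 8) for i in range(8)])


@pytest.fixture(scope="session")
def regular_k3_small():
    return generate_k_regular(2000, 3, seed=11)


@pytest.fixture(scope="session")
def sim_prevalence_ref(params11):
    """Reference quasi-stationary endemic prevalence (mean, se) for SIS at
    tau = gamma = 1 on large 3-regular girth-filtered networks."""
    N = 20000
    net = generate_k_regular(N, 3, seed=42)
    vals = []
    for s in range(4):
        mean_I, _, _ = quasi_stationary_prevalence(
            net, params11, t_burn=100.0, t_meas=350.0, seed=1000 + s)
        vals.append(mean_I / N)
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
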