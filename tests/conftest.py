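import pytest

import isopool as ip


@pytest.fixture(scope="session")
def noiseless_sim() -> ip.SimResult:
    """Full study design, no measurement noise, no pair loss."""
    return ip.simulate_experiment(ip.SimConfig(seed=11).noiseless())


@pytest.fixture(scope="session")
def noiseless_pair_map(noiseless_sim) -> ip.PairMap:
    return ip.build_pair_map(noiseless_sim.pot_table)


@pytest.fixture(scope="session")
def noisy_sim() -> ip.SimResult:
    """Full study design under the default measurement-noise model."""
    return ip.simulate_experiment(ip.SimConfig(seed=5))
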