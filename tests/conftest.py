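import pytest

from oznox.synthetic_fixtures import preset_scenarios, simulate_run


@pytest.fixture(scope="session")
def pc_22_6_run():
    """Noiseless single-species polyunsaturated PC run."""
    return simulate_run(preset_scenarios("pc_22_6"))


@pytest.fixture(scope="session")
def fa_seven_run():
    """Seven coeluting FA 16:1 regioisomers, n-7 dominant."""
    return simulate_run(preset_scenarios("fa_16_1_seven_isomers"))


@pytest.fixture(scope="session")
def coelution_run():
    """LPC 22:4(n-6,9,12,15) coeluting with LPC 18:1(n-9)."""
    return simulate_run(preset_scenarios("lpc_coelution"))


@pytest.fixture(scope="session")
def mix_75_25_run():
    """75/25 n-9/n-7 LPC 18:1 mixture, noiseless."""
    return simulate_run(preset_scenarios("lpc_18_1_75_25"))
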