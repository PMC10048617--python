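import pytest

import dscspg as d


@pytest.fixture(scope="session")
def panel():
    return d.default_panel()


@pytest.fixture(scope="session")
def freqs(panel):
    return d.synthetic_frequencies(panel)


@pytest.fixture(scope="session")
def donors(freqs):
    profs = d.sample_reference_profiles(freqs, 10, 424242)
    for i, p in enumerate(profs):
        p.donor_id = f"DONOR{i:03d}"
    return profs


@pytest.fixture(scope="session")
def at():
    return d.AnalyticalThresholds()


@pytest.fixture()
def cfg():
    return d.SimulationConfig()
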