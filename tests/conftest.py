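import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_barn_records():
    from sowtherm import simulate_barn

    return simulate_barn()
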