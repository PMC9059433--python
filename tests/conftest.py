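import pytest

from pneumovent.engine import Waveform, simulate
from pneumovent.presets import make_preset
from pneumovent.units import GasProperties


@pytest.fixture(scope="session")
def gas() -> GasProperties:
    return GasProperties()


@pytest.fixture(scope="session")
def validation_waveform() -> Waveform:
    """Simulated validation scenario, shared across tests (deterministic)."""
    return simulate(make_preset("validation").resolve())
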