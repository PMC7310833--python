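import pytest

from thermokin.cli_report import load_reference_fixture
from thermokin.units import Temperature


@pytest.fixture(scope="session")
def reference():
    """Bundled printed-value reference characterization."""
    return load_reference_fixture()


@pytest.fixture(scope="session")
def reference_inactivation(reference):
    """(Temperature, printed kin) pairs of the reference inactivation panel."""
    rows = reference["inactivation"]["rows"]
    return [(Temperature(r["temperature_C"]), r["kin_per_min"]) for r in rows]
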