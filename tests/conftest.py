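import pytest

from jointload import (
    DEFAULT_FRACTIONS,
    REFERENCE_SUBJECT,
    PassiveTorqueModel,
    default_table,
    segment_inertia,
)


@pytest.fixture(scope="session")
def seg():
    """Shank+foot inertials of the 1.75 m / 75 kg reference subject."""
    return segment_inertia(REFERENCE_SUBJECT, DEFAULT_FRACTIONS)


@pytest.fixture(scope="session")
def anat():
    """Calibrated reference anatomy table."""
    return default_table()


@pytest.fixture(scope="session")
def passive():
    return PassiveTorqueModel()
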