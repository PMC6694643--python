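import pytest

from famline import study_data


@pytest.fixture(scope="session")
def reference_roster():
    """Roster expanded from the bundled published class-level counts."""
    return study_data.reference_roster()


@pytest.fixture(scope="session")
def reference_sibships():
    """Published sibship totals T=2013, R=891, J=580 with Q=163."""
    return study_data.reference_sibships()
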