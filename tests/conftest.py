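import hypothesis
import pytest

import mapmeta as mm

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def trials():
    """The published trial tables."""
    return mm.fixtures()


@pytest.fixture(scope="session")
def adult_mi():
    """MetaInput of the three adult kidney-transplant trials."""
    return mm.MetaInput.from_trials(mm.adult_trials())


@pytest.fixture(scope="session")
def dyspepsia_mi(trials):
    """MetaInput of the Bond and Opera trials."""
    return mm.MetaInput.from_trials([trials["bond"], trials["opera"]])
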