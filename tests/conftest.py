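import pytest

from ocddi import CohortDDIModel, basecase_config


@pytest.fixture(scope="session")
def basecase():
    """The shipped base-case configuration."""
    return basecase_config()


@pytest.fixture(scope="session")
def fitted(basecase):
    """Base-case model results, fitted once per session."""
    return CohortDDIModel(config=basecase).fit()
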