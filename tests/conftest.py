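import pytest

from gatafam.pipeline import RunConfig, analyze
from gatafam.synthetic import generate_panel


@pytest.fixture(scope="session")
def panel():
    """The default 19-ecotype panel with planted ground truth."""
    return generate_panel(seed=1)


@pytest.fixture(scope="session")
def result(panel):
    """Full pipeline result on the default panel."""
    return analyze(panel, RunConfig(seed=1, bootstrap=50))


@pytest.fixture(scope="session")
def truth(panel):
    return panel.ground_truth
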