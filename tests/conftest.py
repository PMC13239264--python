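import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from mspira.synth import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def demo_bundle():
    """Small synthetic cohort shared across fast tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size cohort under the frozen default configuration."""
    return generate_cohort(GeneratorConfig(seed=3))
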