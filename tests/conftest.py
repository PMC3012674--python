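import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bacpanel import synthetic_data as sim


@pytest.fixture(scope="session")
def planted_genome():
    """Annotated genome with known TCS architecture and category members."""
    return sim.gen_annotated_genome(seed=11)


@pytest.fixture(scope="session")
def assembly_fixture():
    return sim.gen_assembly_fixture(seed=7)
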