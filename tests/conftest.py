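import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from pathwaycurator.fixtures import generate_synthetic_case


@pytest.fixture(scope="session")
def small_case(tmp_path_factory):
    """One small synthetic case shared by read-only tests."""
    out = tmp_path_factory.mktemp("case")
    return generate_synthetic_case(
        seed=11, n_references=3, n_ecs=10, n_holes=2, n_misannotations=1,
        output_dir=out,
    )
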