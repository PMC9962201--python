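import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from arcp450.synthetic_data import default_study_spec, generate_study


@pytest.fixture(scope="session")
def demo_study():
    """The default synthetic demo study, generated once per session."""
    return generate_study(default_study_spec(17))


@pytest.fixture(scope="session")
def demo_study_dir(demo_study, tmp_path_factory):
    """The demo study written to disk."""
    out = tmp_path_factory.mktemp("study")
    paths = demo_study.write(out)
    return paths
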