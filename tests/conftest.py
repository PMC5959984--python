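import pytest

from srs_idp.plan_model import load_plan_quality_table
from srs_idp.study import run_sweep


@pytest.fixture(scope="session")
def plan_table():
    return load_plan_quality_table()


@pytest.fixture(scope="session")
def sweep():
    """The full factorial study table (48 configurations)."""
    return run_sweep()
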