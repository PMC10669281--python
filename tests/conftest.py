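import pytest

from tsto import casestudy as cs
from tsto.quality import summarize_runs


@pytest.fixture(scope="session")
def stage1_plan():
    return cs.stage1_plan()


@pytest.fixture(scope="session")
def stage2_plan():
    return cs.stage2_plan()


@pytest.fixture(scope="session")
def stage1_summary(stage1_plan):
    return summarize_runs(stage1_plan, cs.STAGE1_RESULTS, "ltb")


@pytest.fixture(scope="session")
def stage2_summary(stage2_plan):
    return summarize_runs(stage2_plan, cs.STAGE2_RESULTS, "ltb")
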