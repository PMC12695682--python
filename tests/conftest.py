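import pytest

from nervequant.cohort import packaged_cohort_path, read_cohort_table


@pytest.fixture(scope="session")
def cohort_records():
    return read_cohort_table(packaged_cohort_path())
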