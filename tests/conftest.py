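import pytest

from matepairsv.fixtures import write_fixture_cohort
from matepairsv.io import PipelineConfig
from matepairsv.pipeline import run_cohort_dir

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """The six-patient fixture cohort, materialized once per session."""
    d = tmp_path_factory.mktemp("cohort")
    write_fixture_cohort(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def cohort_results(cohort_dir):
    """Full pipeline results for every fixture patient."""
    return run_cohort_dir(cohort_dir, PipelineConfig())
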