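import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from dacsaug import CohortSpec, generate_cohort, worked_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The hand-checkable micro-cohort."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort for pipeline-level tests."""
    spec = CohortSpec(
        n_clusters=4,
        drugs_per_cluster=3,
        n_candidate_drugs=10,
        n_cell_lines=10,
        n_genes=50,
        n_instances=150,
        seed=11,
    )
    return generate_cohort(spec)
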