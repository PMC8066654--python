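import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cravingqtl import (GenotypeMatrix, SNPInfo, default_cohort_config,
                        reference_panel, reference_risk_model,
                        simulate_cohort)
from cravingqtl.pipeline import make_fixtures


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def ref_model():
    return reference_risk_model()


@pytest.fixture(scope="session")
def cohort():
    """A moderately sized cohort simulated under the default panel."""
    return simulate_cohort(default_cohort_config(seed=42, n_subjects=400))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(out, seed=7)


def toy_matrix(calls: dict[str, list], samples: list[str]) -> GenotypeMatrix:
    frame = pd.DataFrame(calls, index=samples, dtype=object)
    frame.index.name = "sample_id"
    return GenotypeMatrix(frame)


@pytest.fixture
def toy_snp():
    return SNPInfo("rs0001", "GENE1", "A", "G", "toy")
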