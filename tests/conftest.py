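import numpy as np
import pandas as pd
import pytest

from causalrd.cohort import CohortTable, default_codebook
from causalrd.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def cohort805():
    """A default-configuration synthetic cohort at the study size."""
    return generate_cohort(GeneratorConfig(n=805, seed=42))


@pytest.fixture(scope="session")
def cohort_large():
    """A large cohort for asymptotic checks."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=7))


def toy_cohort(y, x, z=None, codebook=None):
    """Assemble a minimal CohortTable from raw vectors.

    ``z`` optionally supplies a binary confounder mapped onto the
    previous-health variable (0 -> good, 1 -> poor).
    """
    codebook = codebook or default_codebook()
    n = len(y)
    data = {
        "participant_id": np.arange(1, n + 1),
        "outcome": np.asarray(y, dtype=int),
        "exposure": np.asarray(x, dtype=int),
    }
    if z is not None:
        data["previous_health"] = np.where(np.asarray(z) == 1, "poor", "good")
    return CohortTable(pd.DataFrame(data), codebook)
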