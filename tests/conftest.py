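import pytest

import hsctrace as h


@pytest.fixture(scope="session")
def cohort():
    """Default ten-patient cohort at reduced per-sample depth (7,500 cells),
    shared across tests that only need realistic structure, not power."""
    return h.simulate_cohort(h.SimConfig(cells_per_sample=250, seed=7))


@pytest.fixture(scope="session")
def norm_cohort(cohort):
    return h.lognormalize(cohort.matrix)
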