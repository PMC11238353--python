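import numpy as np
import pytest

import secondopinion as so


@pytest.fixture(scope="session")
def design_cohort():
    """A cohort with the published study design: 142 SW / 148 NSE cases
    with 24 / 42 pulp exposures."""
    return so.generate_cohort(142, 148, 24, 42, seed=1)


@pytest.fixture(scope="session")
def study():
    """Full study-shaped synthetic data: 25-rater panel calibrated to
    pool-mean macro-F1 0.586 and an AI calibrated to macro-F1 0.71."""
    return so.generate_study(so.StudyConfig(seed=1))


def random_tiny_matrix(rng: np.random.Generator, n_cases=None, n_raters=None):
    """A random small response matrix for enumeration-vs-engine checks."""
    n = int(n_cases if n_cases is not None else rng.integers(3, 7))
    m = int(n_raters if n_raters is not None else rng.integers(2, 5))
    return so.ResponseMatrix(
        case_id=np.array([f"c{i}" for i in range(n)], dtype=object),
        truth=rng.integers(0, 2, size=n),
        rater_ids=tuple(f"r{a}" for a in range(m)),
        responses=rng.integers(0, 2, size=(n, m)),
        ai=rng.integers(0, 2, size=n),
    )
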