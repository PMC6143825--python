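import numpy as np
import pytest

from groupsice.synthetic import (
    CohortConfig,
    generate_precision_spec,
    make_two_group_cohort,
    perturb_for_group,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_panel():
    """Two-group cohort at unit-test scale (P=8, 3+3 subjects)."""
    return make_two_group_cohort(
        7, P=8, n_edges=10, n_flip=3, M_per_group=3, n_t=120
    )


@pytest.fixture(scope="session")
def medium_panel():
    """Cohort sized for solver-behavior checks (P=15, 5+5 subjects, n_t=229)."""
    return make_two_group_cohort(
        11, P=15, n_edges=25, n_flip=4, M_per_group=5, n_t=229
    )


@pytest.fixture(scope="session")
def one_group_specs():
    base = generate_precision_spec(6, 6, 0.3, seed=21)
    other = perturb_for_group(base, {(0, 1)}, 0.3, seed=22)
    return base, other


def random_spd(rng, R, jitter=0.5):
    """Well-conditioned random covariance for solver tests."""
    A = rng.normal(size=(R + 10, R))
    S = A.T @ A / (R + 10)
    return S + jitter * np.eye(R)
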