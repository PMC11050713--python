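import numpy as np
import pytest

import riepath as rp


def random_spd(rng: np.random.Generator, n: int, log_eig_range: float = 2.0) -> np.ndarray:
    """Well-conditioned random SPD matrix with log-eigenvalues in +-range."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eig = np.exp(rng.uniform(-log_eig_range, log_eig_range, size=n))
    return (Q * eig) @ Q.T


@pytest.fixture(scope="session")
def fixture_cohort():
    """The bundled deterministic cohort: expression, sets, survival, truth."""
    return rp.fixture_small()


@pytest.fixture(scope="session")
def fixture_activation(fixture_cohort):
    expr, sets, _, _ = fixture_cohort
    return rp.score_all(expr, sets)
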