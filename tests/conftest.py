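import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient cohort shared across tests (read-only)."""
    from neoresp import GeneratorParams, generate_cohort

    params = GeneratorParams(n_patients=120, seed=7)
    records, cf = generate_cohort(params)
    return params, records, cf


@pytest.fixture(scope="session")
def tiny_fit(small_cohort):
    """A quickly fitted model for integration-level tests."""
    from neoresp import ResponseModel, desk_config

    _, records, _ = small_cohort
    model = ResponseModel(records)
    results = model.fit(desk_config(seed=0, align_epochs=1, response_steps=40,
                                    eval_every=20, folds=3))
    return results


def finite_diff_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at array x."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(x.size):
        d = np.zeros_like(x)
        d.flat[i] = eps
        g.flat[i] = (f(x + d) - f(x - d)) / (2 * eps)
    return g
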