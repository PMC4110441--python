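import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

import clusterbias as cb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_null_design():
    """Three-level design satisfying strong invariance at both levels."""
    return cb.SimulationDesign(
        n_schools=30,
        classes_per_school=3,
        students_per_class=12,
        loadings=[0.8, 0.7, 0.6, 0.5],
        phi=(1.0, 0.3, 0.1),
        residual_var=[[0.5] * 4, [0.0] * 4, [0.0] * 4],
        seed=101,
    )


@pytest.fixture(scope="session")
def biased_design():
    """Level-2 residual bias injected, Level-3 invariant (high signal)."""
    return cb.SimulationDesign(
        n_schools=60,
        classes_per_school=3,
        students_per_class=15,
        loadings=[0.8, 0.7, 0.6, 0.5],
        phi=(1.0, 0.4, 0.1),
        residual_var=[[0.5] * 4, [0.3] * 4, [0.0] * 4],
        seed=5,
    )


@pytest.fixture(scope="session")
def recovery_design():
    """Moderate design with all variance components present."""
    return cb.SimulationDesign(
        n_schools=50,
        classes_per_school=3,
        students_per_class=20,
        loadings=[0.8, 0.7, 0.6, 0.5],
        phi=(1.0, 0.3, 0.1),
        residual_var=[[0.5] * 4, [0.1] * 4, [0.05] * 4],
        seed=7,
    )


@pytest.fixture(scope="session")
def recovery_data(recovery_design):
    return cb.simulate_dataset(recovery_design)


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    models = cb.build_cluster_bias_models(4, [])
    fit = cb.fit_ml(models.baseline, recovery_data)
    assert fit.converged
    return fit


def random_tiny_instance(rng, n_levels=3):
    """A tiny random nested dataset plus random admissible moments."""
    from clusterbias.engine import ImpliedMoments

    p = int(rng.integers(1, 5))
    design = cb.SimulationDesign(
        n_schools=int(rng.integers(1, 4)),
        classes_per_school={"choices": [1, 2, 3]},
        students_per_class={"choices": [1, 2, 3, 4]},
        loadings=rng.uniform(0.4, 0.9, p),
        phi=(1.0, 0.3, 0.1)[:n_levels],
        residual_var=[
            rng.uniform(0.3, 0.8, p),
            rng.uniform(0.0, 0.2, p),
            rng.uniform(0.0, 0.1, p),
        ][:n_levels],
        n_levels=n_levels,
        seed=int(rng.integers(2**31 - 1)),
    )
    data = cb.simulate_dataset(design, seed=rng)
    A = rng.normal(size=(p, p))
    sig = [A @ A.T + np.eye(p)]
    B = rng.normal(size=(p, p)) * 0.3
    sig.append(B @ B.T)
    if n_levels == 3:
        rank3 = int(rng.integers(0, p + 1))  # exercises singular Sigma_3
        C = rng.normal(size=(p, max(rank3, 1))) * 0.4
        sig.append(C @ C.T if rank3 else np.zeros((p, p)))
    moments = ImpliedMoments(rng.normal(size=p), sig)
    return data, moments
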