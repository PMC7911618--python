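import numpy as np
import pytest

from geomaxent import (
    GridSpec,
    OccurrenceSet,
    RasterLayer,
    RasterStack,
    default_scenario,
    make_environment,
    make_true_suitability,
    sample_occurrences,
)


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=4, n_cols=5, x_ll=100.0, y_ll=20.0, cell_size=0.5)


@pytest.fixture
def small_stack(small_spec):
    rng = np.random.default_rng(7)
    layers = [
        RasterLayer(f"v{i}", small_spec, rng.normal(size=small_spec.shape))
        for i in range(3)
    ]
    # one nodata hole shared by extraction logic tests
    layers[1].values[2, 3] = np.nan
    return RasterStack(layers)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def environment(scenario):
    return make_environment(scenario)


@pytest.fixture(scope="session")
def truth(environment, scenario):
    return make_true_suitability(environment, scenario)


@pytest.fixture(scope="session")
def occurrences(truth, scenario):
    return sample_occurrences(truth, scenario.n_presences, seed=2)


@pytest.fixture(scope="session")
def fitted_light(environment, occurrences):
    """One light maximum-entropy fit shared by read-only diagnostics tests."""
    from geomaxent import MaxEnt

    model = MaxEnt.from_stack(
        environment, occurrences, fc="LQH", n_knots=10, n_background=2000, seed=3
    )
    return model, model.fit(rm=1.0, max_iter=300, tol=1e-4)
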